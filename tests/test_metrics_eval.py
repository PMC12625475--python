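"""Volumes, plate thickness, plane placement fraction, and group
comparison statistics."""

import numpy as np
import pytest
import trimesh
from shapely.geometry import Point, box as shapely_box

from stentforge import csg
from stentforge.errors import GeometryError, ParameterError
from stentforge.geometry_ops import Plane, make_box
from stentforge.mesh_core import empty_mesh, make_mesh
from stentforge.metrics_eval import (
    DesignSummary,
    compare_groups,
    format_table,
    min_plate_thickness,
    plane_height_fraction,
    stent_volume_ml,
)


class TestStentVolume:
    def test_cube_is_one_ml(self, cube10):
        assert stent_volume_ml(cube10) == pytest.approx(1.0)

    def test_empty_is_zero(self):
        assert stent_volume_ml(empty_mesh()) == 0.0


class TestMinPlateThickness:
    def test_uniform_slab(self):
        slab = make_box((0, 0, 5), (40, 40, 10))
        footprint = shapely_box(-15, -15, 15, 15)
        assert min_plate_thickness(slab, footprint) == pytest.approx(
            10.0, abs=1e-6
        )

    def test_hemispherical_dent(self):
        """A 4 mm-deep spherical dent in a 10 mm slab leaves 6 mm."""
        slab = make_box((0, 0, 5), (40, 40, 10))
        ball = trimesh.creation.icosphere(subdivisions=4, radius=8.0)
        ball = make_mesh(ball.vertices + np.array([0, 0, 14.0]), ball.faces)
        dented = csg.voxel_boolean(slab, ball, "subtract", resolution=320)
        footprint = Point(0, 0).buffer(5.0)
        assert min_plate_thickness(dented, footprint) == pytest.approx(
            6.0, abs=0.2
        )

    def test_ray_missing_stent_returns_zero(self):
        slab = make_box((0, 0, 5), (10, 10, 10))
        footprint = shapely_box(-20, -20, 20, 20)  # wider than the slab
        assert min_plate_thickness(slab, footprint) == 0.0

    def test_empty_footprint_rejected(self, cube10):
        with pytest.raises(ParameterError):
            min_plate_thickness(cube10, Point(0, 0).buffer(0))

    def test_monotone_in_tongue_size(self, pipeline_run):
        """Plate thickness does not increase as the tongue grows."""
        from stentforge.geometry_ops import TongueParams, boolean_op, \
            make_tongue_mesh
        state = pipeline_run["state"]
        base = pipeline_run["pre_tongue_lower"]
        tongue = state.tongue
        footprint = state.tongue_footprint
        previous = np.inf
        for scale in (0.6, 0.8, 1.0, 1.1, 1.2):
            axes = (tongue.semi_axes[0] * scale, tongue.semi_axes[1],
                    tongue.semi_axes[2] * scale)
            center = tongue.center.copy()
            center[2] = tongue.center[2] + (axes[2] - tongue.semi_axes[2])
            mesh = make_tongue_mesh(
                TongueParams(semi_axes=axes, center=center)
            )
            carved = boolean_op(base, mesh, "subtract", resolution=128)
            t = min_plate_thickness(carved, footprint, grid_spacing_mm=1.0)
            assert t <= previous + 0.3  # voxel-pitch slack
            previous = t


class TestPlaneHeightFraction:
    def test_endpoints(self, cube10):
        gum = np.array([0.0, 0.0, 5.0])  # top face of the cube
        at_gum = Plane([0, 0, 1], 5.0)
        at_occlusal = Plane([0, 0, 1], -5.0)
        assert plane_height_fraction(at_gum, cube10, gum) == pytest.approx(
            0.0, abs=1e-9
        )
        assert plane_height_fraction(at_occlusal, cube10, gum) == \
            pytest.approx(1.0, abs=1e-9)

    def test_vertical_plane_rejected(self, cube10):
        with pytest.raises(GeometryError):
            plane_height_fraction(Plane([1, 0, 0], 0.0), cube10,
                                  np.array([0, 0, 5.0]))


class TestCompareGroups:
    def test_identical_groups(self):
        rep = compare_groups([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert rep["mean_difference_ml"] == pytest.approx(0.0)
        assert rep["p_value"] == pytest.approx(1.0)

    def test_hand_computed_welch_t(self):
        """a={1,2,3}, b={4,5,6}: difference magnitude 3, t = -3.674."""
        rep = compare_groups([1, 2, 3], [4, 5, 6])
        assert abs(rep["mean_difference_ml"]) == pytest.approx(3.0)
        assert rep["welch_t"] == pytest.approx(-3.674, abs=1e-3)

    def test_sem_by_hand(self):
        """SEM of {30,31,32} mL is 1/sqrt(3) = 0.577 mL."""
        s = DesignSummary("g", (30.0, 31.0, 32.0))
        assert s.sem_ml == pytest.approx(0.577, abs=1e-3)
        assert s.sem_ml == pytest.approx(s.sd_ml / np.sqrt(s.n), abs=1e-12)

    def test_antisymmetric_under_swap(self):
        a, b = [10.0, 12.0, 11.0], [14.0, 13.5, 15.0]
        fwd = compare_groups(a, b)
        rev = compare_groups(b, a)
        assert fwd["mean_difference_ml"] == pytest.approx(
            -rev["mean_difference_ml"]
        )
        assert fwd["welch_t"] == pytest.approx(-rev["welch_t"])
        assert fwd["p_value"] == pytest.approx(rev["p_value"])

    def test_small_groups_rejected(self):
        with pytest.raises(ParameterError):
            compare_groups([1.0], [2.0, 3.0])

    def test_table_formatting(self):
        text = format_table([DesignSummary("manual", (30.0, 31.0, 32.0))])
        assert "manual" in text and "31.00" in text
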