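"""Plane fitting, capped cuts, hull expansion, primitives, smoothing,
and the voxel volume oracle."""

import numpy as np
import pytest

from stentforge.errors import GeometryError, ParameterError
from stentforge.geometry_ops import (
    Plane,
    TongueParams,
    expanded_hull,
    fit_plane_pca,
    make_box,
    make_tongue_mesh,
    plane_cut,
    points_inside,
    smooth_protected,
    voxelize_volume_oracle,
)
from stentforge.mesh_core import mesh_volume

from conftest import assert_watertight


class TestFitPlanePCA:
    def test_exact_square(self):
        plane = fit_plane_pca([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        np.testing.assert_allclose(plane.normal, [0, 0, 1], atol=1e-12)
        assert plane.offset == pytest.approx(0.0, abs=1e-12)

    def test_three_point_analytic(self):
        """Plane x+y+z=3: normal (1,1,1)/sqrt(3), offset sqrt(3)."""
        plane = fit_plane_pca([[3, 0, 0], [0, 3, 0], [0, 0, 3]])
        np.testing.assert_allclose(plane.normal, np.ones(3) / np.sqrt(3),
                                   atol=1e-12)
        assert plane.offset == pytest.approx(np.sqrt(3), abs=1e-12)

    def test_small_noise_tilts_normal_like_svd(self):
        """Symmetric z-noise of 0.01 leaves the normal within 0.2 degrees
        of +Z, matching a direct SVD solution."""
        rng = np.random.default_rng(1)
        xy = rng.uniform(-10, 10, size=(200, 2))
        z = rng.normal(0, 0.01, size=200)
        pts = np.column_stack([xy, z])
        plane = fit_plane_pca(pts)
        angle = np.degrees(np.arccos(abs(plane.normal[2])))
        assert angle < 0.2
        # independent oracle: smallest right-singular vector
        _, _, vt = np.linalg.svd(pts - pts.mean(axis=0))
        oracle = vt[-1] * np.sign(vt[-1, 2])
        assert abs(plane.normal @ oracle) > np.cos(np.radians(0.01))

    def test_collinear_points_rejected(self):
        with pytest.raises(GeometryError):
            fit_plane_pca([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]])

    def test_exactly_coplanar_residual_zero(self):
        rng = np.random.default_rng(3)
        pts2 = rng.uniform(-5, 5, size=(50, 2))
        pts = np.column_stack([pts2, 2.0 + 0.5 * pts2[:, 0] - pts2[:, 1]])
        plane = fit_plane_pca(pts)
        assert np.abs(plane.signed_distance(pts)).max() < 1e-10


class TestPlaneCut:
    def test_half_cube(self, cube10):
        half = plane_cut(cube10, Plane([0, 0, 1], 0.0), keep="below")
        assert_watertight(half)
        assert mesh_volume(half) == pytest.approx(500.0, rel=1e-3)

    def test_missing_plane_is_noop_with_flag(self, cube10):
        with pytest.warns(UserWarning):
            out = plane_cut(cube10, Plane([0, 0, 1], -20.0), keep="above")
        assert out.metadata.get("plane_cut_noop") is True
        assert mesh_volume(out) == pytest.approx(1000.0)

    def test_sphere_cap_closed_form(self, sphere10):
        """Cutting a radius-10 sphere at z=5 removes the spherical cap
        pi h^2 (3r - h)/3."""
        below = plane_cut(sphere10, Plane([0, 0, 1], 5.0), keep="below")
        r, h = 10.0, 5.0
        expected = 4.0 / 3.0 * np.pi * r**3 - np.pi * h * h * (3 * r - h) / 3.0
        assert mesh_volume(below) == pytest.approx(expected, rel=0.01)

    @pytest.mark.parametrize("normal,offset", [
        ((0, 0, 1), 2.0), ((1, 1, 1), 1.0), ((0.3, -0.7, 0.9), -1.5),
    ])
    def test_partition_of_convex_solid(self, sphere10, normal, offset):
        """Keep-above plus keep-below volumes equal the whole within 0.5%."""
        plane = Plane(np.asarray(normal, dtype=float), offset)
        above = plane_cut(sphere10, plane, keep="above")
        below = plane_cut(sphere10, plane, keep="below")
        total = mesh_volume(above) + mesh_volume(below)
        assert total == pytest.approx(mesh_volume(sphere10), rel=0.005)


class TestExpandedHull:
    def test_zero_expansion_identity(self, cube10):
        hull = expanded_hull([cube10], 0.0)
        assert mesh_volume(hull) == pytest.approx(1000.0, rel=1e-9)

    def test_scaling_law(self, cube10):
        hull = expanded_hull([cube10], 0.015)
        assert mesh_volume(hull) == pytest.approx(1000.0 * 1.015**3,
                                                  rel=1e-6)

    @pytest.mark.parametrize("fraction", [0.005, 0.015, 0.05])
    def test_cubic_growth_relative_to_unexpanded(self, sphere10, fraction):
        v0 = mesh_volume(expanded_hull([sphere10], 0.0))
        vf = mesh_volume(expanded_hull([sphere10], fraction))
        assert vf / v0 == pytest.approx((1 + fraction) ** 3, rel=1e-9)

    def test_arch_vertices_strictly_inside(self, fast_model):
        """Every input vertex of both jaws ends up inside the 1.5%-expanded
        joint hull."""
        hull = expanded_hull([fast_model.maxilla, fast_model.mandible], 0.015)
        rng = np.random.default_rng(0)
        pts = np.vstack([fast_model.maxilla.vertices,
                         fast_model.mandible.vertices])
        pts = pts[rng.choice(len(pts), size=400, replace=False)]
        assert points_inside(hull, pts).all()

    def test_coplanar_points_rejected(self):
        import trimesh
        from stentforge.mesh_core import make_mesh
        flat = make_mesh(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
            [[0, 1, 2], [0, 2, 3]],
        )
        with pytest.raises(GeometryError):
            expanded_hull([flat], 0.015)


class TestPrimitives:
    @pytest.mark.parametrize("extents,expected", [
        ((10, 10, 10), 1000.0), ((20, 8, 12), 1920.0),
    ])
    def test_box_volumes(self, extents, expected):
        box = make_box((1.0, -2.0, 3.0), extents)
        assert_watertight(box)
        assert len(box.faces) == 12
        assert mesh_volume(box) == pytest.approx(expected)

    def test_rotated_box_volume_unchanged(self):
        ang = np.radians(45)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        box = make_box((0, 0, 0), (10, 10, 10), orientation=rot)
        assert mesh_volume(box) == pytest.approx(1000.0)

    def test_box_rejects_nonpositive_extent(self):
        with pytest.raises(ParameterError):
            make_box((0, 0, 0), (10, 0, 10))

    @pytest.mark.parametrize("axes", [(1, 1, 1), (2, 3, 4), (15, 25, 8)])
    def test_tongue_ellipsoid_volume(self, axes):
        mesh = make_tongue_mesh(TongueParams(semi_axes=axes))
        expected = 4.0 / 3.0 * np.pi * np.prod(axes)
        assert_watertight(mesh)
        assert mesh_volume(mesh) == pytest.approx(expected, rel=0.005)

    def test_tongue_rejects_bad_axes(self):
        with pytest.raises(ParameterError):
            TongueParams(semi_axes=(1.0, -2.0, 3.0))


class TestSmoothProtected:
    def test_fully_protected_mesh_identical(self, cube10):
        out = smooth_protected(cube10, [cube10], protect_distance=0.5,
                               iterations=10)
        np.testing.assert_array_equal(out.vertices, cube10.vertices)

    def test_unprotected_volume_nearly_preserved(self, sphere10):
        """Ten lambda/mu iterations change the volume by < 2%."""
        out = smooth_protected(sphere10, [], protect_distance=0.5,
                               iterations=10)
        assert_watertight(out)
        v0 = mesh_volume(sphere10)
        assert abs(mesh_volume(out) - v0) / v0 < 0.02

    def test_protected_vertices_bit_identical(self, sphere10):
        """Vertices near a protected surface do not move at all; the rest
        do."""
        from scipy.spatial import cKDTree
        protect = make_box((0.0, 0.0, 10.0), (3.0, 3.0, 3.0))
        out = smooth_protected(sphere10, [protect], protect_distance=3.0,
                               iterations=5)
        # the box corners are a subset of the protection samples, so any
        # vertex this close to a corner is certainly protected
        dist, _ = cKDTree(protect.vertices).query(sphere10.vertices)
        near = dist <= 3.0
        assert near.any() and not near.all()
        np.testing.assert_array_equal(out.vertices[near],
                                      sphere10.vertices[near])
        assert not np.array_equal(out.vertices[~near],
                                  sphere10.vertices[~near])

    def test_negative_iterations_rejected(self, cube10):
        with pytest.raises(ParameterError):
            smooth_protected(cube10, [], iterations=-1)


class TestVoxelOracle:
    def test_cube_exact_on_aligned_grid(self, cube10):
        assert voxelize_volume_oracle(cube10, 128) == pytest.approx(
            1000.0, rel=0.01
        )

    def test_sphere(self, sphere10):
        assert voxelize_volume_oracle(sphere10, 128) == pytest.approx(
            mesh_volume(sphere10), rel=0.01
        )

    def test_empty_mesh_is_zero(self):
        from stentforge.mesh_core import empty_mesh
        assert voxelize_volume_oracle(empty_mesh(), 64) == 0.0

    def test_low_resolution_rejected(self, cube10):
        with pytest.raises(ParameterError):
            voxelize_volume_oracle(cube10, 4)
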