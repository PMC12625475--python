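"""STL I/O, watertight repair, and volume computation."""

import struct

import numpy as np
import pytest
import trimesh

from stentforge.errors import MeshFormatError, RepairError, WatertightError
from stentforge.mesh_core import (
    RigidTransform,
    load_stl,
    make_mesh,
    mesh_volume,
    repair_watertight,
    save_stl,
)
from stentforge.synthetic_anatomy import punch_holes

from conftest import assert_watertight


class TestStlIO:
    def test_cube_roundtrip_topology(self, cube10, tmp_path):
        """A 10 mm cube loads back with 8 deduplicated vertices, 12 faces."""
        path = tmp_path / "cube.stl"
        save_stl(cube10, path)
        loaded = load_stl(path)
        assert len(loaded.vertices) == 8
        assert len(loaded.faces) == 12
        assert loaded.volume == pytest.approx(1000.0)

    def test_binary_size_formula(self, cube10, tmp_path):
        """Binary STL is exactly 84 + 50 bytes per triangle."""
        path = tmp_path / "cube.stl"
        save_stl(cube10, path)
        assert path.stat().st_size == 84 + 50 * 12

    def test_ascii_binary_equivalence(self, cube10, tmp_path):
        """ASCII and binary dialects load to identical vertex/face sets."""
        bpath, apath = tmp_path / "b.stl", tmp_path / "a.stl"
        save_stl(cube10, bpath)
        cube10.export(apath, file_type="stl_ascii")
        mb, ma = load_stl(bpath), load_stl(apath)
        vb = np.array(sorted(map(tuple, np.round(mb.vertices, 4))))
        va = np.array(sorted(map(tuple, np.round(ma.vertices, 4))))
        np.testing.assert_allclose(vb, va, atol=1e-4)
        assert len(mb.faces) == len(ma.faces)

    def test_mandible_roundtrip_volume(self, normal_model, tmp_path):
        """Save/load of a generated mandible preserves the signed volume to
        binary-STL (float32) precision."""
        path = tmp_path / "mandible.stl"
        save_stl(normal_model.mandible, path)
        loaded = load_stl(path)
        v0 = mesh_volume(normal_model.mandible)
        assert mesh_volume(loaded) == pytest.approx(v0, rel=5e-6)

    def test_checkpoint_parses_with_independent_reader(self, normal_model,
                                                       tmp_path):
        """A written STL parses with a from-scratch struct-level reader."""
        path = tmp_path / "m.stl"
        save_stl(normal_model.mandible, path)
        raw = path.read_bytes()
        (count,) = struct.unpack_from("<I", raw, 80)
        assert count == len(normal_model.mandible.faces)
        assert len(raw) == 84 + 50 * count
        tri = np.frombuffer(raw[84:], dtype=np.uint8)
        tri = tri.reshape(count, 50)[:, 12:48].copy().view("<f4")
        assert np.isfinite(tri).all()

    def test_empty_and_missing_files_error(self, tmp_path, cube10):
        empty = tmp_path / "empty.stl"
        empty.write_bytes(b"")
        with pytest.raises(MeshFormatError):
            load_stl(empty)
        with pytest.raises(MeshFormatError):
            load_stl(tmp_path / "nope.stl")
        with pytest.raises(MeshFormatError):
            save_stl(make_mesh(np.zeros((0, 3)), np.zeros((0, 3), int)),
                     tmp_path / "e.stl")
        with pytest.raises(MeshFormatError):
            save_stl(cube10, tmp_path / "no_such_dir" / "c.stl")


class TestRepairWatertight:
    def test_cube_with_hole(self, cube10):
        """Deleting one quad face and repairing restores the 1000 mm^3 cube."""
        open_cube = make_mesh(cube10.vertices, cube10.faces[:-2])
        assert not open_cube.is_watertight
        repaired = repair_watertight(open_cube)
        assert_watertight(repaired)
        assert mesh_volume(repaired) == pytest.approx(1000.0, rel=0.01)

    def test_watertight_input_unchanged(self, sphere10):
        repaired = repair_watertight(sphere10)
        v0, v1 = mesh_volume(sphere10), mesh_volume(repaired)
        assert abs(v1 - v0) / v0 < 1e-9

    def test_punched_anatomy_recovers_volume(self, normal_model):
        """Three 2 mm scan holes close with < 0.5% volume change."""
        holed = punch_holes(normal_model.maxilla, n_holes=3, radius_mm=2.0,
                            seed=7)
        assert not holed.is_watertight
        repaired = repair_watertight(holed)
        assert_watertight(repaired)
        v0 = mesh_volume(normal_model.maxilla)
        assert mesh_volume(repaired) == pytest.approx(v0, rel=0.005)

    def test_single_triangle_is_irreparable(self):
        tri = make_mesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        with pytest.raises(RepairError):
            repair_watertight(tri)

    def test_idempotent(self, normal_model):
        holed = punch_holes(normal_model.mandible, 3, 2.0, seed=11)
        once = repair_watertight(holed)
        twice = repair_watertight(once)
        v1, v2 = mesh_volume(once), mesh_volume(twice)
        assert abs(v2 - v1) / v1 < 1e-9


class TestMeshVolume:
    def test_analytic_solids(self, cube10, sphere10):
        assert mesh_volume(cube10) == pytest.approx(1000.0)
        assert mesh_volume(sphere10) == pytest.approx(
            4.0 / 3.0 * np.pi * 1000.0, rel=0.005
        )

    def test_open_mesh_rejected(self, cube10):
        open_cube = make_mesh(cube10.vertices, cube10.faces[:-1])
        with pytest.raises(WatertightError):
            mesh_volume(open_cube)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_invariance(self, normal_model, seed):
        """Volume is invariant under rigid motion to 1e-9 relative."""
        rng = np.random.default_rng(seed)
        mat = trimesh.transformations.rotation_matrix(
            rng.uniform(0, np.pi), rng.normal(size=3)
        )
        xf = RigidTransform(mat[:3, :3], rng.uniform(-30, 30, 3))
        moved = xf.apply_mesh(normal_model.mandible)
        v0 = mesh_volume(normal_model.mandible)
        assert abs(mesh_volume(moved) - v0) / v0 < 1e-9

    def test_rigid_transform_validates_rotation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
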