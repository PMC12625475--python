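"""Synthetic anatomy generator: presets, determinism, landmark/mesh
consistency, articulation."""

import json

import numpy as np
import pytest
from scipy.spatial import cKDTree

from stentforge.errors import ParameterError
from stentforge.mesh_core import mesh_volume, repair_watertight
from stentforge.synthetic_anatomy import (
    PRESETS,
    AnatomyParams,
    articulate,
    generate_anatomy,
    load_anatomy,
)

from conftest import FAST_ANATOMY, assert_watertight


class TestPresets:
    def test_normal_has_full_dentition(self, normal_model):
        """14 tooth landmarks per arch (7 per side, no third molars)."""
        assert len(normal_model.tooth_landmarks("upper")) == 14
        assert len(normal_model.tooth_landmarks("lower")) == 14
        assert_watertight(normal_model.maxilla)
        assert_watertight(normal_model.mandible)

    def test_edentulous_is_toothless(self):
        model = generate_anatomy(preset="edentulous", seed=42, **FAST_ANATOMY)
        assert len(model.tooth_landmarks()) == 0
        assert_watertight(model.maxilla)
        assert_watertight(model.mandible)
        # interincisal reference points still exist (ridge crests)
        assert model.has_landmark("upper_incisor_tip")
        assert model.has_landmark("lower_incisor_tip")

    def test_hypodontia_missing_some_stations(self):
        model = generate_anatomy(preset="hypodontia", seed=42, **FAST_ANATOMY)
        n = len(model.tooth_landmarks())
        assert 0 < n < 28

    def test_class3_mandible_advanced(self):
        """Lower incisor tip sits anterior (+Y) of the upper incisor tip."""
        model = generate_anatomy(preset="class3", seed=42, **FAST_ANATOMY)
        dy = model.landmark("lower_incisor_tip")[1] \
            - model.landmark("upper_incisor_tip")[1]
        assert dy > 0

    def test_unknown_preset_rejected(self):
        with pytest.raises(Exception):
            AnatomyParams(preset="supernumerary")

    def test_third_molars_optional(self):
        model = generate_anatomy(preset="normal", seed=42,
                                 include_third_molars=True, **FAST_ANATOMY)
        assert model.has_landmark("lower_left_third_molar")
        assert model.has_landmark("lower_right_third_molar")


class TestModelInvariants:
    def test_interincisal_distance(self, normal_model):
        assert normal_model.interincisal_mm == pytest.approx(20.0, abs=1e-9)

    def test_landmarks_near_surface(self, normal_model):
        """Every landmark lies within 1 mm of its jaw's surface."""
        for jaw, mesh in (("upper", normal_model.maxilla),
                          ("lower", normal_model.mandible)):
            pts = np.array([v for k, v in normal_model.landmarks.items()
                            if k.startswith(jaw)])
            tree = cKDTree(mesh.vertices)
            dist, _ = tree.query(pts)
            assert dist.max() < 1.0

    def test_deterministic(self):
        a = generate_anatomy(preset="normal", seed=7, **FAST_ANATOMY)
        b = generate_anatomy(preset="normal", seed=7, **FAST_ANATOMY)
        np.testing.assert_array_equal(a.maxilla.vertices, b.maxilla.vertices)
        np.testing.assert_array_equal(a.mandible.faces, b.mandible.faces)
        for k in a.landmarks:
            np.testing.assert_array_equal(a.landmarks[k], b.landmarks[k])

    def test_mirror_symmetry_without_jitter(self):
        """At zero jitter, left/right landmark X-coordinates negate."""
        model = generate_anatomy(preset="normal", seed=1, jitter_mm=0.0,
                                 **FAST_ANATOMY)
        for name, pt in model.landmarks.items():
            if "_left_" not in name:
                continue
            twin = model.landmark(name.replace("_left_", "_right_"))
            assert pt[0] == pytest.approx(-twin[0], abs=1e-9)
            assert pt[1] == pytest.approx(twin[1], abs=1e-9)
            assert pt[2] == pytest.approx(twin[2], abs=1e-9)

    @pytest.mark.parametrize("preset", PRESETS)
    def test_repair_is_noop_on_generated_meshes(self, preset):
        model = generate_anatomy(preset=preset, seed=42, **FAST_ANATOMY)
        for mesh in (model.maxilla, model.mandible):
            v0 = mesh_volume(mesh)
            assert mesh_volume(repair_watertight(mesh)) == pytest.approx(
                v0, rel=1e-9
            )


class TestArticulate:
    def test_exact_target_gap(self, fast_model):
        opened = articulate(fast_model, 20.0)
        assert opened.interincisal_mm == pytest.approx(20.0, abs=1e-6)

    def test_identity_at_current_gap(self, fast_model):
        same = articulate(fast_model, fast_model.interincisal_mm)
        np.testing.assert_allclose(same.mandible.vertices,
                                   fast_model.mandible.vertices, atol=1e-12)

    def test_path_independence(self, fast_model):
        via25 = articulate(articulate(fast_model, 25.0), 20.0)
        direct = articulate(fast_model, 20.0)
        np.testing.assert_allclose(via25.mandible.vertices,
                                   direct.mandible.vertices, atol=1e-9)
        for k in direct.landmarks:
            np.testing.assert_allclose(via25.landmarks[k],
                                       direct.landmarks[k], atol=1e-9)

    def test_rejects_nonpositive_opening(self, fast_model):
        with pytest.raises(ParameterError):
            articulate(fast_model, 0.0)


class TestSidecar:
    def test_save_load_roundtrip(self, fast_model, tmp_path):
        fast_model.save(tmp_path)
        loaded = load_anatomy(tmp_path)
        assert loaded.preset == fast_model.preset
        assert set(loaded.landmarks) == set(fast_model.landmarks)
        np.testing.assert_allclose(
            loaded.landmark("lower_incisor_tip"),
            fast_model.landmark("lower_incisor_tip"), atol=1e-9,
        )
        sidecar = json.loads((tmp_path / "landmarks.json").read_text())
        assert sidecar["units"] == "mm"
        assert sidecar["seed"] == fast_model.seed
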