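"""Shared fixtures.

The full default-resolution pipeline run on the seed-42 normal-occlusion
fixture is expensive (~1 min), so it is executed once per session and every
parameter-echo test reads from it.  Robustness/determinism tests use a
reduced problem size (coarser anatomy and boolean grids) chosen to keep the
whole suite within a few minutes while preserving every geometric property
under test.
"""

from __future__ import annotations

import time

import numpy as np
import pytest
import trimesh

from stentforge.mesh_core import make_mesh, mesh_volume
from stentforge.pipeline import (
    PipelineConfig,
    step1_setup,
    step2_inverse_block,
    step3_separate_upper_lower,
    step4_trim_lower,
    step5_upper_supports,
    step6_add_tail,
    step7_tongue_depression,
    step8_combine,
    step9_smooth,
)
from stentforge.synthetic_anatomy import AnatomyParams, generate_anatomy

# reduced problem size for repeated-run suites (robustness/determinism):
# coarser surface sampling and boolean grids, same design rules
FAST_ANATOMY = dict(mesh_resolution=96)
FAST_CONFIG = dict(voxel_resolution=128)


@pytest.fixture(scope="session")
def cube10():
    box = trimesh.creation.box(extents=[10.0, 10.0, 10.0])
    return make_mesh(box.vertices, box.faces, "cube10")


@pytest.fixture(scope="session")
def sphere10():
    ico = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return make_mesh(ico.vertices, ico.faces, "sphere10")


@pytest.fixture(scope="session")
def normal_model():
    """The seed-42 normal-occlusion fixture at default resolution."""
    return generate_anatomy(AnatomyParams(preset="normal", seed=42))


@pytest.fixture(scope="session")
def fast_model():
    """Reduced-resolution normal fixture for repeated-run suites."""
    return generate_anatomy(AnatomyParams(preset="normal", seed=42,
                                          **FAST_ANATOMY))


@pytest.fixture(scope="session")
def pipeline_run(normal_model, tmp_path_factory):
    """One full default pipeline run with per-step volume bookkeeping."""
    ckpt = tmp_path_factory.mktemp("checkpoints")
    config = PipelineConfig(checkpoint_dir=str(ckpt))
    t0 = time.perf_counter()
    state = step1_setup(normal_model, config)
    state = step2_inverse_block(state)
    vol_block = mesh_volume(state.outline_block)
    state = step3_separate_upper_lower(state)
    vol_upper3 = mesh_volume(state.upper_stent)
    vol_lower3 = mesh_volume(state.lower_stent)
    state = step4_trim_lower(state)
    vol_lower4 = mesh_volume(state.lower_stent)
    state = step5_upper_supports(state)
    state = step6_add_tail(state)
    vol_lower6 = mesh_volume(state.lower_stent)
    pre_tongue_lower = state.lower_stent  # step 7 replaces, not mutates
    state = step7_tongue_depression(state)
    vol_lower7 = mesh_volume(state.lower_stent)
    state = step8_combine(state)
    result = step9_smooth(state)
    wall = time.perf_counter() - t0
    return {
        "model": normal_model,
        "config": config,
        "state": state,
        "result": result,
        "checkpoint_dir": ckpt,
        "pre_tongue_lower": pre_tongue_lower,
        "wall_seconds": wall,
        "volumes": {
            "block": vol_block,
            "upper3": vol_upper3,
            "lower3": vol_lower3,
            "lower4": vol_lower4,
            "lower6": vol_lower6,
            "lower7": vol_lower7,
            "combined": result.part_volumes["combined"],
            "final": result.part_volumes["final"],
        },
    }


def assert_watertight(mesh):
    __tracebackhide__ = True
    assert len(mesh.faces) > 0
    assert mesh.is_watertight and mesh.is_winding_consistent
    assert mesh.volume > 0
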