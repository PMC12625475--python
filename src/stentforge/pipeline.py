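"""The nine-step mouth-opening tongue-depressing stent design workflow.

Given an articulated anatomy model (maxilla + mandible + landmarks), the
pipeline produces a printable stent body:

1. setup/validation at the configured interincisal opening,
2. inverse block: expanded convex hull sliced at PCA occlusal planes with
   the dentition subtracted (the dental impression),
3. separation into upper and lower stent bodies 2 mm above the lower
   central incisor,
4. third-molar trim of the lower stent,
5. left/right upper tooth supports (canine through second molar),
6. posterior tail extension beyond the second molars,
7. tongue-space subtraction with a plate-thickness guarantee,
8. union of the three parts,
9. impression-protected smoothing.

Each step checkpoints its mesh as ``NN_stepname.stl`` when a checkpoint
directory is configured, and the whole chain is deterministic: identical
inputs and configuration give bit-identical volumes.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field
from shapely import affinity
from shapely.geometry import Point, box
from shapely.ops import unary_union

from . import csg
from .errors import (
    CSGError,
    ConstraintError,
    GeometryError,
    LandmarkError,
    ScaleError,
)
from .geometry_ops import (
    Plane,
    TongueParams,
    boolean_op,
    expanded_hull,
    fit_plane_pca,
    make_box,
    make_tongue_mesh,
    plane_cut,
    smooth_protected,
)
from .mesh_core import TriMesh, mesh_volume, repair_watertight, save_stl
from .metrics_eval import min_plate_thickness
from .synthetic_anatomy import AnatomyModel

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineState",
    "StentResult",
    "run_pipeline",
    "step1_setup",
    "step2_inverse_block",
    "step3_separate_upper_lower",
    "step4_trim_lower",
    "step5_upper_supports",
    "step6_add_tail",
    "step7_tongue_depression",
    "step8_combine",
    "step9_smooth",
]

_INTERINCISAL_TOL_MM = 0.5


class PipelineConfig(BaseModel):
    """All numeric design rules of the workflow, in one place (mm)."""

    interincisal_mm: float = Field(default=20.0, gt=0)
    maxilla_plane_fraction: float = Field(default=0.60, gt=0, lt=1)
    mandible_plane_fraction: float = Field(default=0.40, gt=0, lt=1)
    hull_expand_fraction: float = Field(default=0.015, ge=0)
    separation_offset_mm: float = Field(default=2.0, gt=0)
    tail_extension_mm: float = Field(default=10.0, gt=0)
    tongue_posterior_offset_mm: float = Field(default=17.5, gt=0)
    min_plate_thickness_mm: float = Field(default=10.0, gt=0)
    protect_distance_mm: float = Field(default=0.5, gt=0)
    smoothing_iterations: int = Field(default=10, ge=0)
    expansion_mode: Literal["isotropic", "normal_offset"] = "isotropic"
    checkpoint_dir: Optional[str] = None

    # boolean backend grid resolution (voxels along the longest axis)
    voxel_resolution: int = Field(default=256, ge=64)
    # step 4: how far distal to the second molar the trim plane sits
    distal_trim_margin_mm: float = Field(default=1.0, gt=0)
    # step 5: margins and landmark-free fallbacks
    support_margin_mm: float = Field(default=1.0, gt=0)
    support_anterior_fraction: float = Field(default=0.62, gt=0, lt=1)
    support_posterior_fraction: float = Field(default=0.06, ge=0, lt=1)
    support_lingual_clearance_mm: float = Field(default=4.5, gt=0)
    # step 6: tail cross-section padding around the molar rows
    tail_halfwidth_pad_mm: float = Field(default=6.0, gt=0)
    tail_overlap_mm: float = Field(default=8.0, gt=0)
    # step 7: default tongue sizing
    tongue_width_factor: float = Field(default=0.8, gt=0)
    tongue_ap_semi_axis_mm: float = Field(default=25.0, gt=0)
    tongue_vertical_semi_axis_mm: float = Field(default=8.0, gt=0)
    tongue_depth_mm: float = Field(default=3.0, gt=0)
    plate_grid_spacing_mm: float = Field(default=0.5, gt=0)


@dataclass
class StepRecord:
    step_id: int
    name: str
    checkpoint: Optional[str]
    volume_mm3: float


@dataclass
class PipelineState:
    """Checkpointed intermediate state of a pipeline run."""

    anatomy: AnatomyModel
    config: PipelineConfig
    maxillary_plane: Optional[Plane] = None
    mandibular_plane: Optional[Plane] = None
    separation_plane: Optional[Plane] = None
    outline_block: Optional[TriMesh] = None
    upper_stent: Optional[TriMesh] = None
    lower_stent: Optional[TriMesh] = None
    upper_right: Optional[TriMesh] = None
    upper_left: Optional[TriMesh] = None
    tail_box: Optional[TriMesh] = None
    combined: Optional[TriMesh] = None
    final: Optional[TriMesh] = None
    tongue: Optional[TongueParams] = None
    tongue_footprint: object = None
    plate_thickness_mm: Optional[float] = None
    baseline_volumes: dict = field(default_factory=dict)
    step_log: list[StepRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def _checkpoint(self, step_id: int, name: str, mesh: TriMesh):
        path = None
        if self.config.checkpoint_dir:
            os.makedirs(self.config.checkpoint_dir, exist_ok=True)
            path = os.path.join(self.config.checkpoint_dir,
                                f"{step_id:02d}_{name}.stl")
            save_stl(mesh, path)
        vol = mesh_volume(mesh)
        self.step_log.append(StepRecord(step_id, name, path, vol))
        log.info("step %d (%s): volume %.1f mm^3", step_id, name, vol)

    @property
    def last_checkpoint(self) -> Optional[str]:
        for rec in reversed(self.step_log):
            if rec.checkpoint:
                return rec.checkpoint
        return None

    def _warn(self, message: str):
        self.warnings.append(message)
        warnings.warn(message, stacklevel=3)


@dataclass
class StentResult:
    """Final output of a pipeline run."""

    final_stent: TriMesh
    part_volumes: dict[str, float]
    config_used: PipelineConfig
    step_log: list[StepRecord]
    plate_thickness_mm: float
    warnings: list[str] = field(default_factory=list)


def _require_landmarks(anatomy: AnatomyModel, names) -> None:
    for name in names:
        if not anatomy.has_landmark(name):
            raise LandmarkError(name)


def _csg_guard(state: PipelineState, step: str):
    """Context manager: wrap CSG failures with the step id and the last
    good checkpoint path."""
    class _Guard:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(
                exc, (CSGError, ConstraintError, GeometryError,
                      LandmarkError, ScaleError)
            ):
                raise CSGError(str(exc), step=step,
                               checkpoint=state.last_checkpoint) from exc
            return False

    return _Guard()


# ---------------------------------------------------------------------------
# steps


def step1_setup(anatomy: AnatomyModel, config: PipelineConfig | None = None
                ) -> PipelineState:
    """Validate the articulated pose and repair both jaws watertight."""
    config = config or PipelineConfig()
    _require_landmarks(anatomy, ("upper_incisor_tip", "lower_incisor_tip",
                                 "upper_gum_baseline", "lower_gum_baseline"))
    measured = anatomy.interincisal_mm
    if abs(measured - config.interincisal_mm) > _INTERINCISAL_TOL_MM:
        raise ScaleError(measured, config.interincisal_mm)

    anatomy = AnatomyModel(
        maxilla=repair_watertight(anatomy.maxilla),
        mandible=repair_watertight(anatomy.mandible),
        landmarks=dict(anatomy.landmarks),
        preset=anatomy.preset,
        seed=anatomy.seed,
        params=anatomy.params,
    )
    state = PipelineState(anatomy=anatomy, config=config)
    state.baseline_volumes = {
        "maxilla": mesh_volume(anatomy.maxilla),
        "mandible": mesh_volume(anatomy.mandible),
    }
    scan = TriMesh(
        vertices=np.vstack([anatomy.maxilla.vertices,
                            anatomy.mandible.vertices]),
        faces=np.vstack([anatomy.maxilla.faces,
                         anatomy.mandible.faces
                         + len(anatomy.maxilla.vertices)]),
        process=False,
    )
    state._checkpoint(1, "setup", scan)
    return state


def _occlusal_plane(arch: TriMesh, gum_baseline_z: float,
                    fraction: float) -> Plane:
    """PCA best-fit plane of an arch, repositioned at ``fraction`` of the
    gum-to-occlusal vertical extent (measured from the gum baseline)."""
    plane = fit_plane_pca(np.asarray(arch.vertices))
    verts = np.asarray(arch.vertices)
    zmin, zmax = verts[:, 2].min(), verts[:, 2].max()
    occlusal_z = zmin if abs(zmin - gum_baseline_z) > abs(zmax - gum_baseline_z) \
        else zmax
    target_z = gum_baseline_z + fraction * (occlusal_z - gum_baseline_z)
    cx, cy = verts[:, 0].mean(), verts[:, 1].mean()
    # keep the PCA slope; translate so the plane passes through the target
    # height at the arch centroid
    return plane.parallel_through((cx, cy, target_z))


def step2_inverse_block(state: PipelineState) -> PipelineState:
    """Expanded hull of both jaws, sliced at the occlusal planes, with the
    dentition subtracted: the stent outline with its dental impression."""
    cfg = state.config
    anatomy = state.anatomy
    state.maxillary_plane = _occlusal_plane(
        anatomy.maxilla, anatomy.landmark("upper_gum_baseline")[2],
        cfg.maxilla_plane_fraction,
    )
    state.mandibular_plane = _occlusal_plane(
        anatomy.mandible, anatomy.landmark("lower_gum_baseline")[2],
        cfg.mandible_plane_fraction,
    )
    with _csg_guard(state, "step2_inverse_block"):
        if cfg.expansion_mode == "isotropic":
            hull = expanded_hull([anatomy.maxilla, anatomy.mandible],
                                 cfg.hull_expand_fraction)
        else:  # normal_offset: displace hull vertices along vertex normals
            hull = expanded_hull([anatomy.maxilla, anatomy.mandible], 0.0)
            radius = np.linalg.norm(hull.vertices - hull.center_mass,
                                    axis=1).mean()
            verts = hull.vertices + (cfg.hull_expand_fraction * radius
                                     ) * hull.vertex_normals
            hull = TriMesh(vertices=verts, faces=hull.faces, process=False)
        sliced = plane_cut(hull, state.maxillary_plane, keep="below")
        sliced = plane_cut(sliced, state.mandibular_plane, keep="above")
        block = csg.voxel_boolean(
            sliced, [anatomy.maxilla, anatomy.mandible], "subtract",
            cfg.voxel_resolution, provenance="outline_block",
        )
    if len(block.faces) == 0:
        raise GeometryError("inverse block is empty; check plane fractions")
    state.outline_block = block
    state._checkpoint(2, "outline_block", block)
    return state


def step3_separate_upper_lower(state: PipelineState) -> PipelineState:
    """Split the block 2 mm above the lower central incisor, parallel to
    the mandibular occlusal plane."""
    cfg = state.config
    tip = state.anatomy.landmark("lower_incisor_tip")
    sep = state.mandibular_plane.parallel_through(tip).offset_by(
        cfg.separation_offset_mm
    )
    state.separation_plane = sep
    with _csg_guard(state, "step3_separate"):
        upper = plane_cut(state.outline_block, sep, keep="above")
        lower = plane_cut(state.outline_block, sep, keep="below")
    if upper.metadata.get("plane_cut_noop") or lower.metadata.get(
            "plane_cut_noop") or not len(upper.faces) or not len(lower.faces):
        raise GeometryError("separation plane misses the outline block")
    upper.metadata["provenance"] = "upper_stent"
    lower.metadata["provenance"] = "lower_stent"
    state.upper_stent = upper
    state.lower_stent = lower
    state._checkpoint(3, "separated", upper)
    return state


def _vertical_plane_through(point_xy, normal_xy) -> Plane:
    """A plane containing the Z direction: normal is horizontal."""
    n = np.array([normal_xy[0], normal_xy[1], 0.0])
    return Plane.from_point_normal((point_xy[0], point_xy[1], 0.0), n)


def step4_trim_lower(state: PipelineState) -> PipelineState:
    """Remove third molars from the lower stent, one vertical cut per side
    just distal to the second molar.  No-op for sides without a third
    molar (hypodontia, edentulous)."""
    cfg = state.config
    anatomy = state.anatomy
    lower = state.lower_stent
    with _csg_guard(state, "step4_trim_lower"):
        for side in ("left", "right"):
            third = f"lower_{side}_third_molar"
            second = f"lower_{side}_second_molar"
            if not anatomy.has_landmark(third):
                continue
            if not anatomy.has_landmark(second):
                state._warn(f"no {second} landmark; skipping {side} trim")
                continue
            p3 = anatomy.landmark(third)
            p2 = anatomy.landmark(second)
            distal = p3[:2] - p2[:2]
            norm = np.linalg.norm(distal)
            if norm < 1e-9:
                continue
            distal /= norm
            plane = _vertical_plane_through(
                p2[:2] + cfg.distal_trim_margin_mm * distal, distal
            )
            lower = plane_cut(lower, plane, keep="below")
    lower.metadata["provenance"] = "lower_stent_trimmed"
    state.lower_stent = lower
    state._checkpoint(4, "lower_trimmed", lower)
    return state


def _support_planes(state: PipelineState, side: str) -> list[tuple[Plane, str]]:
    """The three vertical carving planes for one upper support side:
    mesial-of-canine, distal-of-second-molar, and lingual parasagittal."""
    cfg = state.config
    anatomy = state.anatomy
    upper = state.upper_stent
    ymin, ymax = upper.vertices[:, 1].min(), upper.vertices[:, 1].max()
    yext = ymax - ymin

    canine = f"upper_{side}_canine"
    if anatomy.has_landmark(canine):
        y_mesial = anatomy.landmark(canine)[1] + cfg.support_margin_mm
    else:
        state._warn(f"no {canine} landmark; using arch-fraction plane")
        y_mesial = ymin + cfg.support_anterior_fraction * yext

    molar = f"upper_{side}_second_molar"
    if anatomy.has_landmark(molar):
        y_distal = anatomy.landmark(molar)[1] - cfg.support_margin_mm
    else:
        state._warn(f"no {molar} landmark; using arch-fraction plane")
        y_distal = ymin + cfg.support_posterior_fraction * yext

    row = [anatomy.landmark(f"upper_{side}_{tooth}")
           for tooth in ("canine", "first_premolar", "second_premolar",
                         "first_molar", "second_molar")
           if anatomy.has_landmark(f"upper_{side}_{tooth}")]
    if row:
        x_lingual = min(abs(p[0]) for p in row) - cfg.support_lingual_clearance_mm
        x_lingual = max(x_lingual, 1.0)
    else:
        xext = upper.vertices[:, 0].max() - upper.vertices[:, 0].min()
        x_lingual = 0.18 * xext
    sign = 1.0 if side == "left" else -1.0

    return [
        (_vertical_plane_through((0.0, y_mesial), (0.0, 1.0)), "below"),
        (_vertical_plane_through((0.0, y_distal), (0.0, 1.0)), "above"),
        (_vertical_plane_through((sign * x_lingual, 0.0), (sign, 0.0)), "above"),
    ]


def step5_upper_supports(state: PipelineState) -> PipelineState:
    """Carve the left and right upper tooth supports (canine, premolars,
    first two molars) out of the upper stent with three vertical planes
    per side."""
    with _csg_guard(state, "step5_upper_supports"):
        supports = {}
        for side in ("left", "right"):
            mesh = state.upper_stent
            for plane, keep in _support_planes(state, side):
                mesh = plane_cut(mesh, plane, keep=keep)
            mesh.metadata["provenance"] = f"upper_{side}_support"
            supports[side] = mesh
    state.upper_left = supports["left"]
    state.upper_right = supports["right"]
    both = TriMesh(
        vertices=np.vstack([supports["left"].vertices,
                            supports["right"].vertices]),
        faces=np.vstack([supports["left"].faces,
                         supports["right"].faces
                         + len(supports["left"].vertices)]),
        process=False,
    )
    state._checkpoint(5, "upper_supports", both)
    return state


def _posterior_reference(state: PipelineState):
    """The most posterior second-molar landmark of the lower arch, with
    graceful fallbacks for partially/fully edentulous cases."""
    anatomy = state.anatomy
    for tooth in ("second_molar", "first_molar"):
        pts = [anatomy.landmark(f"lower_{side}_{tooth}")
               for side in ("left", "right")
               if anatomy.has_landmark(f"lower_{side}_{tooth}")]
        if pts:
            return min(pts, key=lambda p: p[1])
    state._warn("no lower molar landmarks; tail extends from the stent's "
                "posterior edge")
    lower = state.lower_stent
    ymin = lower.vertices[:, 1].min()
    return np.array([0.0, ymin + 5.0, 0.0])


def step6_add_tail(state: PipelineState) -> PipelineState:
    """Fuse a posterior tail box extending beyond the second molars onto
    the lower stent (the tongue-depressing blade's reach)."""
    cfg = state.config
    ref = _posterior_reference(state)
    lower = state.lower_stent

    molar_x = [state.anatomy.landmark(f"lower_{side}_{tooth}")[0]
               for side in ("left", "right")
               for tooth in ("second_molar", "first_molar")
               if state.anatomy.has_landmark(f"lower_{side}_{tooth}")]
    if molar_x:
        half_w = max(abs(x) for x in molar_x) + cfg.tail_halfwidth_pad_mm
    else:
        half_w = 0.45 * (lower.vertices[:, 0].max()
                         - lower.vertices[:, 0].min())

    y_back = ref[1] - cfg.tail_extension_mm
    y_front = ref[1] + cfg.tail_overlap_mm
    # plate band: between the mandibular and separation planes at the arch
    # centroid
    cx, cy = lower.vertices[:, 0].mean(), lower.vertices[:, 1].mean()

    def plane_z(plane):
        nx, ny, nz = plane.normal
        return (plane.offset - nx * cx - ny * cy) / nz

    z_lo = plane_z(state.mandibular_plane)
    z_hi = plane_z(state.separation_plane)
    box = make_box(
        center=((0.0, (y_back + y_front) / 2.0, (z_lo + z_hi) / 2.0)),
        extents=(2 * half_w, y_front - y_back, z_hi - z_lo),
    )
    state.tail_box = box
    with _csg_guard(state, "step6_add_tail"):
        lower = boolean_op(lower, box, "union", cfg.voxel_resolution,
                           provenance="lower_with_tail")
    state.lower_stent = lower
    state._checkpoint(6, "lower_with_tail", lower)
    return state


def _default_tongue(state: PipelineState) -> TongueParams:
    """Auto-placed tongue: centered on the lower teeth, translated
    posteriorly so its tip stays behind the incisors, sized from the
    inter-molar width, sunk ``tongue_depth_mm`` into the plate top."""
    cfg = state.config
    anatomy = state.anatomy
    teeth = anatomy.tooth_landmarks("lower")
    if teeth:
        centroid = np.mean(list(teeth.values()), axis=0)
    else:
        centroid = anatomy.landmark("lower_incisor_tip")

    molar_x = [anatomy.landmark(f"lower_{side}_first_molar")[0]
               for side in ("left", "right")
               if anatomy.has_landmark(f"lower_{side}_first_molar")]
    if len(molar_x) == 2:
        half_width = abs(molar_x[0] - molar_x[1]) / 2.0
    else:
        lower = state.lower_stent
        half_width = 0.3 * (lower.vertices[:, 0].max()
                            - lower.vertices[:, 0].min())

    a = cfg.tongue_width_factor * half_width
    b = cfg.tongue_ap_semi_axis_mm
    c = cfg.tongue_vertical_semi_axis_mm

    nx, ny, nz = state.separation_plane.normal
    cx = centroid[0]
    cy = centroid[1] - cfg.tongue_posterior_offset_mm
    sep_z = (state.separation_plane.offset - nx * cx - ny * cy) / nz
    cz = sep_z + c - cfg.tongue_depth_mm
    return TongueParams(
        semi_axes=(a, b, c),
        center=np.array([cx, cy, cz]),
        posterior_offset=cfg.tongue_posterior_offset_mm,
    )


def _plate_region(lower: TriMesh, min_length_mm: float, bounds_poly,
                  pitch: float = 1.0, shrink: float = 0.75):
    """XY polygon where the (pre-carve) lower stent is plate material.

    A column counts as plate if its total vertical material length is at
    least ``min_length_mm``; dental-impression seats (thin by design) and
    off-stent space are excluded.  The region is shrunk by ``shrink`` mm so
    thickness rays stay clear of impression walls.
    """
    minx, miny, maxx, maxy = bounds_poly.bounds
    nx = max(int(np.ceil((maxx - minx) / pitch)), 1)
    ny = max(int(np.ceil((maxy - miny) / pitch)), 1)
    x0 = minx + csg._NUDGE[0] * pitch
    y0 = miny + csg._NUDGE[1] * pitch
    length, hit = csg.column_inside_lengths(lower, x0, y0,
                                            pitch, pitch, nx, ny)
    good = hit & (length >= min_length_mm)
    if not good.any():
        return None
    gi, gj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    px = x0 + (gi + 0.5) * pitch
    py = y0 + (gj + 0.5) * pitch
    cells = [box(x - pitch / 2, y - pitch / 2, x + pitch / 2, y + pitch / 2)
             for x, y in zip(px[good], py[good])]
    region = unary_union(cells).buffer(0.01).buffer(-shrink)
    return None if region.is_empty else region


def step7_tongue_depression(state: PipelineState,
                            tongue: TongueParams | None = None
                            ) -> PipelineState:
    """Subtract the tongue-space ellipsoid from the lower stent and verify
    the remaining plate thickness."""
    cfg = state.config
    tongue = tongue or _default_tongue(state)
    state.tongue = tongue
    mesh = make_tongue_mesh(tongue)

    # depression footprint: XY region where the ellipsoid dips below the
    # separation plane
    a, b, c = tongue.semi_axes
    nrm = state.separation_plane.normal
    cx, cy, cz = tongue.center
    sep_z = (state.separation_plane.offset - nrm[0] * cx - nrm[1] * cy) / nrm[2]
    depth = sep_z - (cz - c)  # how deep the ellipsoid bottom dives
    if depth <= 0:
        raise ConstraintError(
            "tongue mesh does not reach the plate top; nothing depressed"
        )
    rho = np.sqrt(max(1.0 - ((cz - sep_z) / c) ** 2, 1e-9)) \
        if cz > sep_z else 1.0
    footprint = affinity.scale(
        Point(cx, cy).buffer(1.0, quad_segs=64), a * rho, b * rho
    )
    # the plate-thickness guarantee applies where plate material actually
    # reaches the top surface; dental-impression trenches and the open
    # posterior edge are not plate
    plate = _plate_region(state.lower_stent, cfg.min_plate_thickness_mm,
                          footprint)
    if plate is None:
        raise ConstraintError("tongue depression lies entirely off the plate")
    footprint = footprint.intersection(plate)
    if footprint.is_empty or footprint.area <= 0:
        raise ConstraintError("tongue depression lies entirely off the plate")
    state.tongue_footprint = footprint

    with _csg_guard(state, "step7_tongue"):
        lower = boolean_op(state.lower_stent, mesh, "subtract",
                           cfg.voxel_resolution, provenance="lower_depressed")

    thickness = min_plate_thickness(lower, footprint,
                                    cfg.plate_grid_spacing_mm)
    state.plate_thickness_mm = thickness
    if thickness < cfg.min_plate_thickness_mm:
        raise ConstraintError(
            f"plate thickness {thickness:.2f} mm is below the required "
            f"{cfg.min_plate_thickness_mm:.1f} mm; reduce the tongue "
            f"semi-axes or depth"
        )
    state.lower_stent = lower
    state._checkpoint(7, "lower_depressed", lower)
    return state


def step8_combine(state: PipelineState) -> PipelineState:
    """Union the upper-left and upper-right supports with the lower stent."""
    cfg = state.config
    with _csg_guard(state, "step8_combine"):
        combined = csg.voxel_boolean(
            state.lower_stent, [state.upper_left, state.upper_right],
            "union", cfg.voxel_resolution, provenance="combined",
        )
    n_parts = len(combined.split(only_watertight=False))
    if n_parts > 1:
        state._warn(f"combined stent has {n_parts} connected components")
    state.combined = combined
    state._checkpoint(8, "combined", combined)
    return state


def step9_smooth(state: PipelineState) -> StentResult:
    """Smooth sharp edges while keeping the dental impression bit-identical,
    then assemble the result."""
    cfg = state.config
    final = smooth_protected(
        state.combined,
        [state.anatomy.maxilla, state.anatomy.mandible],
        protect_distance=cfg.protect_distance_mm,
        iterations=cfg.smoothing_iterations,
    )
    final.metadata["provenance"] = "final_stent"
    state.final = final
    state._checkpoint(9, "final", final)
    part_volumes = {
        "upper_left": mesh_volume(state.upper_left),
        "upper_right": mesh_volume(state.upper_right),
        "lower": mesh_volume(state.lower_stent),
        "combined": mesh_volume(state.combined),
        "final": mesh_volume(final),
    }
    return StentResult(
        final_stent=final,
        part_volumes=part_volumes,
        config_used=cfg,
        step_log=state.step_log,
        plate_thickness_mm=state.plate_thickness_mm,
        warnings=state.warnings,
    )


def run_pipeline(anatomy: AnatomyModel,
                 config: PipelineConfig | None = None,
                 tongue: TongueParams | None = None) -> StentResult:
    """Execute steps 1-9 and return the final stent."""
    state = step1_setup(anatomy, config)
    state = step2_inverse_block(state)
    state = step3_separate_upper_lower(state)
    state = step4_trim_lower(state)
    state = step5_upper_supports(state)
    state = step6_add_tail(state)
    state = step7_tongue_depression(state, tongue)
    state = step8_combine(state)
    return step9_smooth(state)
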