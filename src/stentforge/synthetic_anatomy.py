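"""Deterministic parametric generator of articulated dental anatomy.

Stands in for intraoral scans of articulated stone models: produces a
watertight maxilla and mandible plus a named landmark map, articulated at a
requested interincisal opening (default 20 mm, the bite-block opening used
when scanning real models).

Anatomical frame (used throughout the package):

* +Z: occlusal / superior,
* +Y: anterior,
* +X: patient-left.

Each jaw is built implicitly on a voxel grid — a gum ridge swept along a
parabolic arch curve, plus one superellipsoid per tooth station (7 per
side: central/lateral incisor, canine, two premolars, two molars; third
molars optional) — and remeshed with marching cubes, which guarantees
watertightness.  Landmarks are the analytic tooth apex points, so they are
consistent with the mesh surface to within half a voxel regardless of the
jitter seed.

Presets mirror the anatomy spectrum of a real patient population:
``normal`` occlusion, ``edentulous`` (no teeth; interincisal reference
points sit on the ridge crests), ``hypodontia`` (a seeded subset of ten
candidate stations removed), and ``class3`` malocclusion (mandible advanced
6 mm anteriorly).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field
from scipy.spatial import cKDTree

from . import csg
from .errors import LandmarkError, ParameterError
from .mesh_core import TriMesh, load_stl, save_stl

__all__ = [
    "PRESETS",
    "AnatomyParams",
    "AnatomyModel",
    "generate_anatomy",
    "articulate",
    "punch_holes",
    "load_anatomy",
]

PRESETS = ("edentulous", "hypodontia", "normal", "class3")

#: tooth stations from the midline outwards, one list entry per side
_TOOTH_ORDER = (
    "central_incisor",
    "lateral_incisor",
    "canine",
    "first_premolar",
    "second_premolar",
    "first_molar",
    "second_molar",
)

# per-type bucco-lingual half-width (mm); molars are broader than incisors
_TOOTH_RADIAL = {
    "central_incisor": 3.2,
    "lateral_incisor": 3.0,
    "canine": 3.4,
    "first_premolar": 3.8,
    "second_premolar": 4.0,
    "first_molar": 4.8,
    "second_molar": 4.8,
    "third_molar": 4.5,
}

# stations a hypodontia case may congenitally lack (10 candidates)
_HYPODONTIA_CANDIDATES = (
    ("upper", "left", "lateral_incisor"),
    ("upper", "right", "lateral_incisor"),
    ("lower", "left", "lateral_incisor"),
    ("lower", "right", "lateral_incisor"),
    ("upper", "left", "second_premolar"),
    ("upper", "right", "second_premolar"),
    ("lower", "left", "second_premolar"),
    ("lower", "right", "second_premolar"),
    ("upper", "left", "second_molar"),
    ("upper", "right", "second_molar"),
)

_CLASS3_ADVANCE_MM = 6.0  # anterior mandibular advancement
_RIDGE_HALF_WIDTH_MM = 4.5
_TOOTH_EMBED_MM = 1.5  # how deep a tooth root sinks into the ridge


class AnatomyParams(BaseModel):
    """Generator parameters (mm).  Defaults approximate an adult arch."""

    arch_width_mm: float = Field(default=55.0, gt=0)
    arch_depth_mm: float = Field(default=45.0, gt=0)
    tooth_height_mm: float = Field(default=8.0, gt=0)
    ridge_height_mm: float = Field(default=12.0, gt=0)
    interincisal_mm: float = Field(default=20.0, gt=0)
    preset: Literal["edentulous", "hypodontia", "normal", "class3"] = "normal"
    seed: int = Field(default=42, ge=0)
    jitter_mm: float = Field(default=0.2, ge=0)
    include_third_molars: bool = False
    mesh_resolution: int = Field(default=160, ge=32)


@dataclass
class AnatomyModel:
    """Articulated maxilla + mandible with a named landmark map."""

    maxilla: TriMesh
    mandible: TriMesh
    landmarks: dict[str, np.ndarray]
    preset: str = "normal"
    seed: int = 0
    params: AnatomyParams | None = field(default=None, repr=False)

    def landmark(self, name: str) -> np.ndarray:
        if name not in self.landmarks:
            raise LandmarkError(name)
        return np.asarray(self.landmarks[name], dtype=float)

    def has_landmark(self, name: str) -> bool:
        return name in self.landmarks

    def tooth_landmarks(self, jaw: str | None = None) -> dict[str, np.ndarray]:
        """Landmarks at tooth apices (excludes incisor-tip references and
        gum baselines)."""
        out = {}
        for name, pt in self.landmarks.items():
            if name.endswith(("_tip", "_baseline")):
                continue
            if jaw is None or name.startswith(jaw):
                out[name] = np.asarray(pt, dtype=float)
        return out

    @property
    def interincisal_mm(self) -> float:
        return float(self.landmark("upper_incisor_tip")[2]
                     - self.landmark("lower_incisor_tip")[2])

    def save(self, out_dir: os.PathLike | str) -> list[str]:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        paths = []
        for name, mesh in (("maxilla.stl", self.maxilla),
                           ("mandible.stl", self.mandible)):
            path = os.path.join(out_dir, name)
            save_stl(mesh, path)
            paths.append(path)
        sidecar = {
            "landmarks": {k: [float(x) for x in v]
                          for k, v in self.landmarks.items()},
            "units": "mm",
            "preset": self.preset,
            "seed": int(self.seed),
        }
        jpath = os.path.join(out_dir, "landmarks.json")
        with open(jpath, "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)
        paths.append(jpath)
        return paths


def load_anatomy(in_dir: os.PathLike | str) -> AnatomyModel:
    """Read maxilla.stl / mandible.stl / landmarks.json from a directory."""
    in_dir = os.fspath(in_dir)
    maxilla = load_stl(os.path.join(in_dir, "maxilla.stl"))
    mandible = load_stl(os.path.join(in_dir, "mandible.stl"))
    jpath = os.path.join(in_dir, "landmarks.json")
    if not os.path.isfile(jpath):
        raise LandmarkError("landmarks.json")
    with open(jpath) as fh:
        sidecar = json.load(fh)
    landmarks = {k: np.asarray(v, dtype=float)
                 for k, v in sidecar.get("landmarks", {}).items()}
    return AnatomyModel(maxilla, mandible, landmarks,
                        preset=sidecar.get("preset", "unknown"),
                        seed=int(sidecar.get("seed", 0)))


# ---------------------------------------------------------------------------
# arch curve helpers


def _arch_curve(width: float, depth: float, y_apex: float, n: int = 801):
    """Sampled parabolic arch: apex anterior at (0, y_apex), posterior ends
    at (+-width/2, y_apex - depth).  Returns (points xy, cumulative arc
    length), sampled from the left end to the right end."""
    s = np.linspace(-1.0, 1.0, n)
    x = 0.5 * width * s
    y = y_apex - depth * s * s
    xy = np.column_stack([x, y])
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return xy, arc


def _stations_one_side(xy, arc, n_teeth: int):
    """Tooth station centers/tangents for the patient-left half (x > 0),
    from the midline outwards; the right side is an exact mirror."""
    half = arc[-1] / 2.0
    spacing = half / n_teeth
    targets = half + (np.arange(n_teeth) + 0.5) * spacing
    idx = np.searchsorted(arc, targets)
    idx = np.clip(idx, 1, len(xy) - 1)
    centers = xy[idx]
    tangents = xy[idx] - xy[idx - 1]
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return centers, tangents, spacing


# ---------------------------------------------------------------------------
# implicit jaw construction


def _build_jaw(jaw: str, params: AnatomyParams, rng: np.random.Generator,
               teeth_present: set[tuple[str, str]]):
    """Voxelise one jaw (ridge + teeth) and return (mesh, landmarks).

    ``jaw`` is "upper" or "lower".  Both jaws are built teeth-up in a local
    frame with the gum baseline at z=0, then the upper jaw is flipped
    (z -> -z) into the anatomical frame.  ``teeth_present`` holds
    (side, tooth) pairs to instantiate.
    """
    upper = jaw == "upper"
    # maxillary arch is slightly wider/deeper: ~2 mm overjet
    width = params.arch_width_mm + (4.0 if upper else 0.0)
    depth = params.arch_depth_mm + (2.0 if upper else 0.0)
    y_apex = 25.0 + (2.0 if upper else 0.0)
    ridge_h = params.ridge_height_mm
    tooth_h = params.tooth_height_mm
    ridge_half_width = _RIDGE_HALF_WIDTH_MM
    if not teeth_present:
        # an edentulous stone model presents a taller, broader residual
        # ridge in place of the dentition: the scan captures the full
        # vestibular width down to the trimmed model base, so the arch
        # envelope is comparable to a dentate model of the same patient
        ridge_h += tooth_h
        ridge_half_width = 6.0

    xy, arc = _arch_curve(width, depth, y_apex)
    n_teeth = 8 if params.include_third_molars else 7
    centers_l, tangents_l, spacing = _stations_one_side(xy, arc, n_teeth)

    order = list(_TOOTH_ORDER) + (
        ["third_molar"] if params.include_third_molars else []
    )

    teeth = []  # (side, tooth_name, center_xy, tangent_xy, semi_axes)
    for k, tooth in enumerate(order):
        # draw jitter for both sides regardless of presence so the random
        # stream (and hence every other tooth) is preset-independent
        for side, sign in (("left", 1.0), ("right", -1.0)):
            jit = rng.normal(0.0, params.jitter_mm, size=3) \
                if params.jitter_mm > 0 else np.zeros(3)
            if (side, tooth) not in teeth_present:
                continue
            cx = sign * centers_l[k, 0] + jit[0]
            cy = centers_l[k, 1] + jit[1]
            tan = tangents_l[k] * np.array([sign, 1.0])
            semi = np.array([
                0.48 * spacing,
                _TOOTH_RADIAL[tooth],
                0.5 * (tooth_h + _TOOTH_EMBED_MM),
            ])
            semi *= 1.0 + 0.02 * jit[2] / max(params.jitter_mm, 1e-9) \
                if params.jitter_mm > 0 else 1.0
            teeth.append((side, tooth, np.array([cx, cy]), tan, semi))

    # grid in the local (teeth-up) frame
    margin = 3.0
    lo = np.array([-width / 2 - _RIDGE_HALF_WIDTH_MM - margin,
                   y_apex - depth - _RIDGE_HALF_WIDTH_MM - margin,
                   -margin])
    hi = np.array([width / 2 + _RIDGE_HALF_WIDTH_MM + margin,
                   y_apex + _RIDGE_HALF_WIDTH_MM + margin,
                   ridge_h + tooth_h + margin])
    pitch = float((hi - lo).max()) / params.mesh_resolution
    shape = np.ceil((hi - lo) / pitch).astype(int)
    origin = lo + csg._NUDGE * pitch

    gx = origin[0] + (np.arange(shape[0]) + 0.5) * pitch
    gy = origin[1] + (np.arange(shape[1]) + 0.5) * pitch
    gz = origin[2] + (np.arange(shape[2]) + 0.5) * pitch

    # gum ridge: elliptical tube around the arch curve, baseline at z=0
    gxx, gyy = np.meshgrid(gx, gy, indexing="ij")
    tree = cKDTree(xy)
    dxy, _ = tree.query(np.column_stack([gxx.ravel(), gyy.ravel()]), k=1)
    dxy = dxy.reshape(shape[0], shape[1])
    zc = ridge_h / 2.0
    rad2 = ((dxy / ridge_half_width) ** 2)[:, :, None] \
        + (((gz - zc) / zc) ** 2)[None, None, :]
    occ = rad2 <= 1.0

    landmarks: dict[str, np.ndarray] = {}
    ridge_top = ridge_h
    apex_z = ridge_top - _TOOTH_EMBED_MM + tooth_h  # tooth tip height

    for side, tooth, cxy, tan, semi in teeth:
        cz = ridge_top - _TOOTH_EMBED_MM + semi[2] - (semi[2] * 2 - tooth_h
                                                      - _TOOTH_EMBED_MM) / 2
        cz = ridge_top - _TOOTH_EMBED_MM + 0.5 * (tooth_h + _TOOTH_EMBED_MM)
        # local bbox of this tooth in grid indices
        r = semi.max() + pitch
        i0 = np.clip(np.searchsorted(gx, cxy[0] - r), 0, shape[0])
        i1 = np.clip(np.searchsorted(gx, cxy[0] + r), 0, shape[0])
        j0 = np.clip(np.searchsorted(gy, cxy[1] - r), 0, shape[1])
        j1 = np.clip(np.searchsorted(gy, cxy[1] + r), 0, shape[1])
        k0 = np.clip(np.searchsorted(gz, cz - r), 0, shape[2])
        k1 = np.clip(np.searchsorted(gz, cz + r), 0, shape[2])
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        lx = gx[i0:i1] - cxy[0]
        ly = gy[j0:j1] - cxy[1]
        lz = gz[k0:k1] - cz
        # rotate into the tooth frame: X along the arch tangent
        nrm = np.array([-tan[1], tan[0]])
        X = lx[:, None] * tan[0] + ly[None, :] * tan[1]
        Y = lx[:, None] * nrm[0] + ly[None, :] * nrm[1]
        f = (np.abs(X / semi[0]) ** 3 + np.abs(Y / semi[1]) ** 3)[:, :, None] \
            + (np.abs(lz / semi[2]) ** 3)[None, None, :]
        occ[i0:i1, j0:j1, k0:k1] |= f <= 1.0
        landmarks[f"{jaw}_{side}_{tooth}"] = np.array(
            [cxy[0], cxy[1], cz + semi[2]]
        )

    mesh = csg.remesh_occupancy(occ, origin, pitch, provenance=f"{jaw}_jaw")

    # interincisal reference: right central incisor apex, or the anterior
    # ridge crest for an edentulous arch
    ref = landmarks.get(f"{jaw}_right_central_incisor")
    if ref is None:
        ref = np.array([0.0, y_apex, ridge_top])
    landmarks[f"{jaw}_incisor_tip"] = ref.copy()
    landmarks[f"{jaw}_gum_baseline"] = np.array([0.0, y_apex, 0.0])

    # map the local teeth-up frame into the anatomical frame
    if upper:
        flip = np.diag([1.0, 1.0, -1.0])
        mesh = TriMesh(vertices=mesh.vertices @ flip, faces=mesh.faces[:, ::-1],
                       process=False)
        mesh.metadata["provenance"] = "upper_jaw"
        landmarks = {k: v * np.array([1.0, 1.0, -1.0])
                     for k, v in landmarks.items()}
    return mesh, landmarks


def generate_anatomy(params: AnatomyParams | None = None, **kwargs) -> AnatomyModel:
    """Generate an articulated anatomy model for a preset.

    Deterministic: equal parameters (including seed) give bit-identical
    meshes and landmarks.
    """
    if params is None:
        params = AnatomyParams(**kwargs)
    elif kwargs:
        params = params.model_copy(update=kwargs)
    if params.preset not in PRESETS:
        raise ParameterError(f"unknown preset {params.preset!r}; "
                             f"choose from {PRESETS}")
    rng = np.random.default_rng(params.seed)

    order = list(_TOOTH_ORDER) + (
        ["third_molar"] if params.include_third_molars else []
    )
    full = {(side, tooth) for tooth in order for side in ("left", "right")}
    present = {"upper": set(full), "lower": set(full)}
    if params.preset == "edentulous":
        present = {"upper": set(), "lower": set()}
    elif params.preset == "hypodontia":
        missing_idx = rng.choice(len(_HYPODONTIA_CANDIDATES), size=4,
                                 replace=False)
        for i in missing_idx:
            jaw, side, tooth = _HYPODONTIA_CANDIDATES[i]
            present[jaw].discard((side, tooth))

    maxilla, upper_lm = _build_jaw("upper", params, rng, present["upper"])
    mandible, lower_lm = _build_jaw("lower", params, rng, present["lower"])

    landmarks = {**upper_lm, **lower_lm}

    # place the jaws: upper fixed with its occlusal reference at +gap/2,
    # lower with its reference at -gap/2
    gap = params.interincisal_mm
    dz_u = gap / 2.0 - upper_lm["upper_incisor_tip"][2]
    dz_l = -gap / 2.0 - lower_lm["lower_incisor_tip"][2]
    maxilla.vertices = maxilla.vertices + np.array([0.0, 0.0, dz_u])
    mandible.vertices = mandible.vertices + np.array([0.0, 0.0, dz_l])
    for k in landmarks:
        if k.startswith("upper"):
            landmarks[k] = landmarks[k] + np.array([0.0, 0.0, dz_u])
        else:
            landmarks[k] = landmarks[k] + np.array([0.0, 0.0, dz_l])

    if params.preset == "class3":
        adv = np.array([0.0, _CLASS3_ADVANCE_MM, 0.0])
        mandible.vertices = mandible.vertices + adv
        for k in landmarks:
            if k.startswith("lower"):
                landmarks[k] = landmarks[k] + adv

    model = AnatomyModel(maxilla, mandible, landmarks,
                         preset=params.preset, seed=params.seed, params=params)
    return articulate(model, params.interincisal_mm)


def articulate(model: AnatomyModel, interincisal_mm: float) -> AnatomyModel:
    """Rigidly translate the mandible along Z so the incisor-tip gap equals
    ``interincisal_mm``.  Landmarks move with the mesh; path-independent."""
    if interincisal_mm <= 0:
        raise ParameterError("interincisal opening must be positive")
    current = model.interincisal_mm
    dz = current - float(interincisal_mm)  # move mandible down to open more
    shift = np.array([0.0, 0.0, dz])
    mandible = model.mandible.copy()
    mandible.vertices = mandible.vertices + shift
    landmarks = {
        k: (np.asarray(v, dtype=float) + shift if k.startswith("lower")
            else np.asarray(v, dtype=float).copy())
        for k, v in model.landmarks.items()
    }
    return AnatomyModel(mandible=mandible, maxilla=model.maxilla.copy(),
                        landmarks=landmarks, preset=model.preset,
                        seed=model.seed, params=model.params)


def punch_holes(mesh: TriMesh, n_holes: int = 3, radius_mm: float = 2.0,
                seed: int = 0) -> TriMesh:
    """Corrupt-fixture helper: delete patches of faces to emulate scan holes.

    Picks ``n_holes`` seed vertices and removes every face whose centroid
    lies within ``radius_mm``; the result is open and exercises
    :func:`stentforge.mesh_core.repair_watertight`.
    """
    rng = np.random.default_rng(seed)
    verts = np.asarray(mesh.vertices)
    centers = verts[rng.choice(len(verts), size=int(n_holes), replace=False)]
    centroids = verts[mesh.faces].mean(axis=1)
    keep = np.ones(len(mesh.faces), dtype=bool)
    for c in centers:
        keep &= np.linalg.norm(centroids - c, axis=1) > float(radius_mm)
    out = TriMesh(vertices=verts.copy(), faces=mesh.faces[keep], process=False)
    out.remove_unreferenced_vertices()
    out.metadata["provenance"] = "hole_punched"
    return out
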