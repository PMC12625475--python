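"""Quantitative stent evaluation: volumes, plate thickness, plane placement,
and inter-run variability summaries.

Volumes are reported in mL (1 mL = 1000 mm^3), matching how fabricated
stents are compared across design trials; the variability measure is the
standard error of the mean (SEM) of the volumes within a group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import stats
from shapely.geometry import Polygon

from . import csg
from .errors import GeometryError, ParameterError, WatertightError
from .geometry_ops import Plane
from .mesh_core import TriMesh, is_watertight, mesh_volume

__all__ = [
    "DesignSummary",
    "stent_volume_ml",
    "min_plate_thickness",
    "plane_height_fraction",
    "compare_groups",
    "format_table",
    "plot_group_volumes",
]


@dataclass(frozen=True)
class DesignSummary:
    """Descriptive statistics of one group of stent volumes (mL)."""

    label: str
    volumes_ml: tuple[float, ...]
    mean_volume_ml: float = field(init=False)
    sd_ml: float = field(init=False)
    sem_ml: float = field(init=False)

    def __post_init__(self):
        vols = tuple(float(v) for v in self.volumes_ml)
        if len(vols) == 0:
            raise ParameterError("a design summary needs at least one volume")
        object.__setattr__(self, "volumes_ml", vols)
        arr = np.asarray(vols)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        object.__setattr__(self, "mean_volume_ml", float(arr.mean()))
        object.__setattr__(self, "sd_ml", sd)
        object.__setattr__(self, "sem_ml", sd / np.sqrt(len(arr)))

    @property
    def n(self) -> int:
        return len(self.volumes_ml)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "mean_volume_ml": self.mean_volume_ml,
            "sd_ml": self.sd_ml,
            "sem_ml": self.sem_ml,
            "volumes_ml": list(self.volumes_ml),
        }


def stent_volume_ml(mesh: TriMesh) -> float:
    """Watertight mesh volume in mL."""
    return mesh_volume(mesh) / 1000.0


def min_plate_thickness(lower_stent: TriMesh, footprint: Polygon,
                        grid_spacing_mm: float = 0.5) -> float:
    """Minimum vertical material thickness over a footprint region.

    Casts a vertical (occlusal-axis) ray at every ``grid_spacing_mm`` lattice
    point inside ``footprint`` (an XY polygon under the tongue depression)
    and measures the total inside-length of its intersection with the stent.
    Returns the minimum over the lattice, or 0.0 if any ray misses the stent
    entirely.
    """
    if footprint is None or footprint.is_empty or footprint.area <= 0:
        raise ParameterError("footprint polygon is empty")
    if not is_watertight(lower_stent):
        raise WatertightError("lower stent")
    dx = float(grid_spacing_mm)
    minx, miny, maxx, maxy = footprint.bounds
    nx = max(int(np.ceil((maxx - minx) / dx)), 1)
    ny = max(int(np.ceil((maxy - miny) / dx)), 1)
    # lattice centers, nudged off axis-aligned mesh edges so ray-crossing
    # parity stays clean
    x0 = minx + csg._NUDGE[0] * dx
    y0 = miny + csg._NUDGE[1] * dx
    gi, gj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    px = x0 + (gi.ravel() + 0.5) * dx
    py = y0 + (gj.ravel() + 0.5) * dx
    wanted = shapely.contains_xy(footprint, px, py).reshape(nx, ny)
    if not wanted.any():
        raise ParameterError("no lattice points fall inside the footprint")

    length, hit = csg.column_inside_lengths(lower_stent, x0, y0,
                                            dx, dx, nx, ny)
    if not hit[wanted].all():
        return 0.0
    return float(length[wanted].min())


def plane_height_fraction(plane: Plane, arch: TriMesh,
                          gum_baseline) -> float:
    """Where a plane sits along an arch's gum-to-occlusal vertical extent.

    0 at the gum baseline, 1 at the occlusal extreme (the arch vertex
    farthest from the baseline along Z); the plane height is evaluated at
    the arch centroid's XY position.
    """
    gz = float(np.asarray(gum_baseline, dtype=float)[2])
    verts = np.asarray(arch.vertices)
    zmin, zmax = float(verts[:, 2].min()), float(verts[:, 2].max())
    # occlusal extreme: farther of the two Z extremes from the gum baseline
    oz = zmin if abs(zmin - gz) > abs(zmax - gz) else zmax
    if abs(oz - gz) < 1e-9:
        raise GeometryError("arch has no vertical extent above the gum baseline")
    cx, cy = verts[:, 0].mean(), verts[:, 1].mean()
    nx, ny, nz = plane.normal
    if abs(nz) < 1e-9:
        raise GeometryError("plane is vertical; height fraction undefined")
    plane_z = (plane.offset - nx * cx - ny * cy) / nz
    return float((plane_z - gz) / (oz - gz))


def compare_groups(volumes_a, volumes_b,
                   label_a: str = "A", label_b: str = "B") -> dict:
    """Welch two-sample comparison of stent-volume groups (mL).

    Returns per-group descriptive summaries, the mean difference (A - B),
    the Welch t statistic and p-value, and a 95% confidence interval for
    the difference.
    """
    a = np.asarray(list(volumes_a), dtype=float)
    b = np.asarray(list(volumes_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs at least 2 volumes")
    sa = DesignSummary(label_a, tuple(a))
    sb = DesignSummary(label_b, tuple(b))
    diff = sa.mean_volume_ml - sb.mean_volume_ml
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    se = float(np.sqrt(va + vb))
    if se < 1e-300:  # both groups constant
        t = 0.0 if abs(diff) < 1e-300 else np.inf * np.sign(diff)
        p = 1.0 if abs(diff) < 1e-300 else 0.0
        df = float(len(a) + len(b) - 2)
        ci = (diff, diff)
    else:
        df = float((va + vb) ** 2 / (va ** 2 / (len(a) - 1)
                                     + vb ** 2 / (len(b) - 1)))
        t = float(diff / se)
        p = float(2.0 * stats.t.sf(abs(t), df))
        tcrit = float(stats.t.ppf(0.975, df))
        ci = (diff - tcrit * se, diff + tcrit * se)
    return {
        "groups": [sa.to_dict(), sb.to_dict()],
        "mean_difference_ml": float(diff),
        "welch_t": t,
        "p_value": p,
        "df": df,
        "ci95_ml": [float(ci[0]), float(ci[1])],
    }


def format_table(summaries) -> str:
    """Plain-text table of group summaries."""
    rows = [f"{'group':<16}{'n':>4}{'mean mL':>10}{'sd mL':>9}{'sem mL':>9}"]
    for s in summaries:
        rows.append(
            f"{s.label:<16}{s.n:>4}{s.mean_volume_ml:>10.2f}"
            f"{s.sd_ml:>9.3f}{s.sem_ml:>9.3f}"
        )
    return "\n".join(rows)


def report_json(summaries, path=None) -> str:
    text = json.dumps([s.to_dict() for s in summaries], indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def plot_group_volumes(summaries, path):
    """Bar chart of group mean volumes with SEM error bars (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    labels = [s.label for s in summaries]
    means = [s.mean_volume_ml for s in summaries]
    sems = [s.sem_ml for s in summaries]
    ax.bar(labels, means, yerr=sems, capsize=4, color="#4878a8")
    ax.set_ylabel("stent volume (mL)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
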