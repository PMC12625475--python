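"""Geometric primitives composed by the stent-design workflow.

PCA occlusal-plane fitting, capped plane cuts, expanded convex hulls,
robust mesh booleans, box/tongue primitives, feature-protected Taubin
smoothing, and the independent voxel volume oracle used in testing.
All lengths are millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from . import csg
from .errors import GeometryError, ParameterError, WatertightError
from .mesh_core import (
    RigidTransform,
    TriMesh,
    boundary_edges,
    empty_mesh,
    is_watertight,
    make_mesh,
    mesh_volume,
    _dedup,
)

__all__ = [
    "Plane",
    "TongueParams",
    "fit_plane_pca",
    "plane_cut",
    "expanded_hull",
    "boolean_op",
    "make_box",
    "make_tongue_mesh",
    "smooth_protected",
    "voxelize_volume_oracle",
    "points_inside",
]

#: operands with at most this many faces combined go through the exact BSP
#: boolean; larger pairs use the voxel-remeshing backend
EXACT_BOOLEAN_MAX_FACES = 512


@dataclass(frozen=True)
class Plane:
    """Oriented infinite plane: points p with ``normal . p == offset``."""

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm < 1e-12:
            raise ParameterError("plane normal must be a nonzero vector")
        object.__setattr__(self, "normal", n / norm)
        object.__setattr__(self, "offset", float(self.offset) / norm)

    @classmethod
    def from_point_normal(cls, point, normal) -> "Plane":
        n = np.asarray(normal, dtype=float)
        return cls(n, float(n @ np.asarray(point, dtype=float)))

    @property
    def point(self) -> np.ndarray:
        """A point on the plane (foot of the origin perpendicular)."""
        return self.normal * self.offset

    def signed_distance(self, points) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.normal - self.offset

    def parallel_through(self, point) -> "Plane":
        return Plane.from_point_normal(point, self.normal)

    def offset_by(self, distance_mm: float) -> "Plane":
        return Plane(self.normal, self.offset + float(distance_mm))


@dataclass(frozen=True)
class TongueParams:
    """Ellipsoidal tongue-space primitive.

    ``semi_axes`` are (lateral, anteroposterior, vertical) half-lengths in
    mm; ``posterior_offset`` is how far behind the lower-teeth centroid the
    ellipsoid center sits by default so its tip stays behind the incisors.
    """

    semi_axes: tuple[float, float, float]
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    posterior_offset: float = 17.5

    def __post_init__(self):
        axes = tuple(float(a) for a in self.semi_axes)
        if len(axes) != 3 or any(a <= 0 for a in axes):
            raise ParameterError("tongue semi-axes must be 3 positive lengths")
        object.__setattr__(self, "semi_axes", axes)
        object.__setattr__(self, "center",
                           np.asarray(self.center, dtype=float).reshape(3))
        object.__setattr__(self, "orientation",
                           np.asarray(self.orientation, dtype=float).reshape(3, 3))


def fit_plane_pca(points) -> Plane:
    """Best-fit plane through a point cloud by principal component analysis.

    The normal is the covariance eigenvector with the smallest eigenvalue,
    with its sign chosen to point along +Z (the occlusal/superior axis);
    the plane passes through the centroid.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise GeometryError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    # rank check: collinear points have two near-zero eigenvalues
    scale = max(evals[-1], 1e-30)
    if evals[1] / scale < 1e-12:
        raise GeometryError("points are collinear or coincident; no unique plane")
    normal = evecs[:, 0]
    if normal[2] < 0 or (normal[2] == 0 and (normal[0] < 0 or
                                             (normal[0] == 0 and normal[1] < 0))):
        normal = -normal
    return Plane.from_point_normal(centroid, normal)


def _cap_open_boundary(mesh: TriMesh) -> TriMesh:
    """Close every boundary loop with a fan to its loop centroid.

    Each directed boundary edge (a, b) is covered by triangle (b, a, apex),
    so winding stays consistent and every edge becomes two-face.  For the
    planar loops produced by a plane cut this reproduces the polygon's
    signed area exactly, so volumes are exact even for non-convex sections.
    """
    bedges = boundary_edges(mesh)
    if len(bedges) == 0:
        return mesh
    nv = len(mesh.vertices)
    # group boundary vertices into loops (connected components)
    ii = np.concatenate([bedges[:, 0], bedges[:, 1]])
    jj = np.concatenate([bedges[:, 1], bedges[:, 0]])
    graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(nv, nv))
    _, labels = connected_components(graph, directed=False)
    new_verts = [mesh.vertices]
    new_faces = [mesh.faces]
    for lab in np.unique(labels[bedges[:, 0]]):
        sel = labels[bedges[:, 0]] == lab
        loop_edges = bedges[sel]
        apex_idx = nv + len(new_verts) - 1
        centroid = mesh.vertices[np.unique(loop_edges)].mean(axis=0)
        new_verts.append(centroid[None, :])
        new_faces.append(
            np.column_stack(
                [loop_edges[:, 1], loop_edges[:, 0],
                 np.full(len(loop_edges), apex_idx)]
            )
        )
    return make_mesh(np.vstack(new_verts), np.vstack(new_faces),
                     mesh.metadata.get("provenance", ""))


def plane_cut(mesh: TriMesh, plane: Plane, keep: str = "above") -> TriMesh:
    """Cut a watertight mesh by a plane, keeping one side, capped.

    ``keep`` is "above" (the side the normal points to) or "below".  A plane
    that misses the mesh entirely returns the input unchanged with a
    ``plane_cut_noop`` metadata flag and a warning; a plane with the whole
    mesh on the discarded side returns an empty mesh.
    """
    if keep not in ("above", "below"):
        raise ParameterError("keep must be 'above' or 'below'")
    if mesh is None or len(mesh.faces) == 0:
        return empty_mesh("plane_cut")
    if not is_watertight(mesh):
        raise WatertightError(mesh.metadata.get("provenance", "mesh"))
    normal = plane.normal if keep == "above" else -plane.normal
    sd = np.asarray(mesh.vertices, dtype=float) @ normal - (
        plane.offset if keep == "above" else -plane.offset
    )
    tol = 1e-9
    if sd.min() >= -tol:
        warnings.warn("plane_cut: plane misses the mesh; returning input",
                      stacklevel=2)
        out = mesh.copy()
        out.metadata["plane_cut_noop"] = True
        return out
    if sd.max() <= tol:
        warnings.warn("plane_cut: entire mesh discarded", stacklevel=2)
        return empty_mesh("plane_cut")
    sliced = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=normal, plane_origin=plane.point, cap=False
    )
    verts, faces = _dedup(np.asarray(sliced.vertices),
                          np.asarray(sliced.faces), decimals=9)
    open_mesh = make_mesh(verts, faces, mesh.metadata.get("provenance", ""))
    capped = _cap_open_boundary(open_mesh)
    if capped.volume < 0:
        capped.invert()
    if not capped.is_watertight:
        capped = csg._stitch_t_vertices(capped)
    if not is_watertight(capped):
        raise GeometryError("plane cut produced a non-watertight mesh")
    return capped


def expanded_hull(meshes, expand_fraction: float = 0.015) -> TriMesh:
    """Convex hull of all input vertices, inflated uniformly.

    The hull is scaled by (1 + expand_fraction) about its volume centroid,
    so hull volume grows exactly by (1 + f)^3.
    """
    if not isinstance(meshes, (list, tuple)):
        meshes = [meshes]
    pts = np.vstack([np.asarray(m.vertices, dtype=float) for m in meshes
                     if len(m.vertices)])
    if len(pts) < 4:
        raise GeometryError("need at least 4 points for a 3D hull")
    try:
        hull = trimesh.convex.convex_hull(pts)
    except Exception as exc:  # qhull degenerate input
        raise GeometryError(f"degenerate hull (coplanar input?): {exc}") from exc
    if hull.volume <= 0 or not hull.is_watertight:
        raise GeometryError("degenerate hull (coplanar input?)")
    center = hull.center_mass
    verts = center + (1.0 + float(expand_fraction)) * (hull.vertices - center)
    out = make_mesh(verts, hull.faces, "expanded_hull")
    if out.volume < 0:
        out.invert()
    return out


def boolean_op(a: TriMesh, b: TriMesh, mode: str,
               resolution: int = 256,
               provenance: str = "boolean") -> TriMesh:
    """Watertight boolean of two watertight meshes.

    Small operand pairs go through the exact BSP backend; large ones are
    voxel-remeshed on a shared grid (``resolution`` voxels along the longest
    axis).  An empty result (e.g. self-subtraction) is a legal empty mesh.
    """
    if mode not in ("union", "subtract", "intersect"):
        raise ParameterError(f"unknown boolean mode {mode!r}")
    a_empty = a is None or len(a.faces) == 0
    b_empty = b is None or len(b.faces) == 0
    if a_empty and b_empty:
        return empty_mesh(provenance)
    if a_empty:
        return b.copy() if mode == "union" else empty_mesh(provenance)
    if b_empty:
        return empty_mesh(provenance) if mode == "intersect" else a.copy()
    for name, m in (("first", a), ("second", b)):
        if not is_watertight(m):
            raise WatertightError(f"{name} boolean operand")
    if len(a.faces) + len(b.faces) <= EXACT_BOOLEAN_MAX_FACES:
        out = csg.bsp_boolean(a, b, mode, provenance)
        if out is not None:
            return out
        warnings.warn("exact boolean failed validation; using voxel backend",
                      stacklevel=2)
    return csg.voxel_boolean(a, b, mode, resolution, provenance)


def make_box(center, extents, orientation=None) -> TriMesh:
    """Watertight 12-triangle cuboid."""
    ext = np.asarray(extents, dtype=float).reshape(3)
    if np.any(ext <= 0):
        raise ParameterError("box extents must be positive")
    box = trimesh.creation.box(extents=ext)
    verts = np.asarray(box.vertices)
    if orientation is not None:
        rot = np.asarray(orientation, dtype=float).reshape(3, 3)
        verts = verts @ rot.T
    verts = verts + np.asarray(center, dtype=float).reshape(3)
    return make_mesh(verts, box.faces, "box")


def make_tongue_mesh(params: TongueParams, subdivisions: int = 3) -> TriMesh:
    """Ellipsoidal tongue-space mesh (icosphere scaled by the semi-axes)."""
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions)
    # an inscribed icosphere under-counts volume (~0.9% at level 3); scale
    # radially so the discrete volume matches the analytic 4/3*pi*a*b*c
    calib = (4.0 / 3.0 * np.pi / sphere.volume) ** (1.0 / 3.0)
    verts = np.asarray(sphere.vertices) * (calib * np.asarray(params.semi_axes))
    verts = verts @ np.asarray(params.orientation).T + params.center
    return make_mesh(verts, sphere.faces, "tongue")


def _surface_samples(mesh: TriMesh) -> np.ndarray:
    """Vertices plus face centroids and edge midpoints: a dense, deterministic
    sampling of the surface for proximity queries."""
    tri = mesh.vertices[mesh.faces]
    centroids = tri.mean(axis=1)
    mids = mesh.vertices[mesh.edges_unique].mean(axis=1)
    return np.vstack([mesh.vertices, centroids, mids])


def smooth_protected(mesh: TriMesh, protected_surfaces,
                     protect_distance: float = 0.5,
                     iterations: int = 10,
                     lamb: float = 0.5, mu: float = -0.53) -> TriMesh:
    """Taubin smoothing that leaves vertices near protected surfaces fixed.

    Vertices within ``protect_distance`` mm of any protected surface are
    bit-identical in the output; the rest undergo ``iterations`` rounds of
    the lambda/mu (shrink/inflate) uniform-Laplacian update, which nearly
    preserves volume.  Topology is untouched, so watertightness survives.
    """
    if iterations < 0:
        raise ParameterError("iterations must be >= 0")
    if not is_watertight(mesh):
        raise WatertightError(mesh.metadata.get("provenance", "mesh"))
    verts = np.array(mesh.vertices, dtype=float)
    if iterations == 0:
        return mesh.copy()
    if not isinstance(protected_surfaces, (list, tuple)):
        protected_surfaces = [protected_surfaces]
    protected = np.zeros(len(verts), dtype=bool)
    samples = [_surface_samples(p) for p in protected_surfaces
               if p is not None and len(p.faces)]
    if samples:
        tree = cKDTree(np.vstack(samples))
        dist, _ = tree.query(verts, k=1)
        protected = dist <= float(protect_distance)

    # uniform Laplacian as a row-normalised adjacency matrix
    edges = mesh.edges_unique
    ii = np.concatenate([edges[:, 0], edges[:, 1]])
    jj = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = coo_matrix((np.ones(len(ii)), (ii, jj)),
                     shape=(len(verts), len(verts))).tocsr()
    degree = np.asarray(adj.sum(axis=1)).ravel()
    degree[degree == 0] = 1.0
    free = ~protected

    original = verts.copy()
    for _ in range(int(iterations)):
        for factor in (lamb, mu):
            mean_nb = adj.dot(verts) / degree[:, None]
            verts[free] += factor * (mean_nb[free] - verts[free])
    verts[protected] = original[protected]
    out = make_mesh(verts, mesh.faces,
                    mesh.metadata.get("provenance", "") or "smoothed")
    if out.volume < 0:
        out.invert()
    return out


def voxelize_volume_oracle(mesh: TriMesh, resolution: int = 256) -> float:
    """Independent parity-ray-cast volume estimate in mm^3.

    Counts voxel centers inside the mesh on a grid spanning exactly the
    mesh bounding box and multiplies by the voxel volume.  Used as the
    cross-check for divergence-theorem volumes throughout the test-suite.
    """
    if mesh is not None and len(mesh.faces) and not is_watertight(mesh):
        raise WatertightError(mesh.metadata.get("provenance", "mesh"))
    return csg.voxel_volume(mesh, resolution)


def points_inside(mesh: TriMesh, points) -> np.ndarray:
    """Boolean mask: which query points are inside the closed mesh.

    Parity of surface crossings above each point along +Z.  Points are
    nudged laterally by 1e-7 mm so queries exactly on mesh edges do not
    break the parity count.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if mesh is None or len(mesh.faces) == 0 or len(pts) == 0:
        return np.zeros(len(pts), dtype=bool)
    tri = mesh.vertices[mesh.faces]
    px = pts[:, 0] + 1e-7
    py = pts[:, 1] + 1.3e-7
    crossings = np.zeros(len(pts), dtype=np.int64)
    chunk = max(1, 2_000_000 // max(len(pts), 1))
    for start in range(0, len(tri), chunk):
        t = tri[start:start + chunk]
        ax, ay = t[:, 0, 0][:, None], t[:, 0, 1][:, None]
        bx, by = t[:, 1, 0][:, None], t[:, 1, 1][:, None]
        cx, cy = t[:, 2, 0][:, None], t[:, 2, 1][:, None]
        area2 = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
        ok = np.abs(area2) > 1e-14
        w0 = ((cx - bx) * (py - by) - (cy - by) * (px - bx))
        w1 = ((ax - cx) * (py - cy) - (ay - cy) * (px - cx))
        w2 = area2 - w0 - w1
        with np.errstate(invalid="ignore", divide="ignore"):
            w0n, w1n, w2n = w0 / area2, w1 / area2, w2 / area2
            inside = ok & (w0n >= 0) & (w1n >= 0) & (w2n >= 0)
            z = (w0n * t[:, 0, 2][:, None] + w1n * t[:, 1, 2][:, None]
                 + w2n * t[:, 2, 2][:, None])
            crossings += np.sum(inside & (z > pts[:, 2]), axis=0)
    return crossings % 2 == 1
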