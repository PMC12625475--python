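"""Triangle-mesh data model, STL I/O, watertight repair, and volume.

Every geometric object in the pipeline is a :class:`trimesh.Trimesh` in
millimetre units.  STL carries no unit metadata, so coordinates are taken
as millimetres verbatim and never rescaled.  A free-text provenance label
(which pipeline step produced the mesh) travels in ``mesh.metadata``.

Watertight here means: closed (every edge shared by exactly two faces),
consistently wound, and outward-oriented so the signed divergence-theorem
volume is positive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import MeshFormatError, RepairError, WatertightError

__all__ = [
    "TriMesh",
    "RigidTransform",
    "load_stl",
    "save_stl",
    "repair_watertight",
    "mesh_volume",
    "is_watertight",
    "empty_mesh",
    "make_mesh",
    "boundary_edges",
]

#: The pipeline's mesh container.
TriMesh = trimesh.Trimesh

# vertices closer than this (mm) are considered the same point when
# deduplicating STL triangle soup
_DEDUP_DECIMALS = 6


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: ``p -> rotation @ p + translation`` (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        tra = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(rot) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper orthonormal (det = +1)")
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 form."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def apply_mesh(self, mesh: TriMesh) -> TriMesh:
        out = mesh.copy()
        out.apply_transform(self.matrix)
        return out

    @classmethod
    def translation_only(cls, vec) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(vec, dtype=float))


def make_mesh(vertices, faces, provenance: str = "") -> TriMesh:
    """Build a TriMesh without trimesh's automatic processing."""
    mesh = trimesh.Trimesh(
        vertices=np.asarray(vertices, dtype=float),
        faces=np.asarray(faces, dtype=np.int64).reshape(-1, 3),
        process=False,
    )
    if provenance:
        mesh.metadata["provenance"] = provenance
    return mesh


def empty_mesh(provenance: str = "empty") -> TriMesh:
    """The zero-volume result of e.g. self-subtraction."""
    return make_mesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64),
                     provenance)


def _dedup(vertices: np.ndarray, faces: np.ndarray,
           decimals: int = _DEDUP_DECIMALS):
    """Merge vertices equal after rounding; drop degenerate faces."""
    if len(vertices) == 0:
        return vertices, faces
    key = np.round(np.asarray(vertices, dtype=float), decimals)
    uniq, inverse = np.unique(key, axis=0, return_inverse=True)
    faces = inverse[np.asarray(faces, dtype=np.int64)]
    # degenerate: repeated indices or numerically zero area
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    faces = faces[ok]
    tri = uniq[faces]
    area2 = np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    faces = faces[area2 > 1e-12]
    # drop exact duplicate faces (same vertex set)
    sorted_faces = np.sort(faces, axis=1)
    _, keep = np.unique(sorted_faces, axis=0, return_index=True)
    faces = faces[np.sort(keep)]
    # drop unreferenced vertices
    used = np.unique(faces)
    remap = -np.ones(len(uniq), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return uniq[used], remap[faces]


def load_stl(path: os.PathLike | str) -> TriMesh:
    """Read a binary or ASCII STL; vertices deduplicated, units taken as mm."""
    path = os.fspath(path)
    if not os.path.isfile(path):
        raise MeshFormatError(f"STL file not found: {path}")
    if os.path.getsize(path) == 0:
        raise MeshFormatError(f"STL file is empty: {path}")
    try:
        raw = trimesh.load(path, file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise MeshFormatError(f"could not parse STL file {path}: {exc}") from exc
    if isinstance(raw, trimesh.Scene):
        geoms = list(raw.geometry.values())
        if not geoms:
            raise MeshFormatError(f"no geometry in STL file {path}")
        raw = trimesh.util.concatenate(geoms)
    verts, faces = _dedup(np.asarray(raw.vertices), np.asarray(raw.faces))
    if len(faces) == 0:
        raise MeshFormatError(f"no valid triangles in STL file {path}")
    return make_mesh(verts, faces, provenance=os.path.basename(path))


def save_stl(mesh: TriMesh, path: os.PathLike | str) -> None:
    """Write binary STL (84 + 50 bytes/triangle)."""
    if mesh is None or len(mesh.faces) == 0:
        raise MeshFormatError("refusing to write an empty mesh to STL")
    path = os.fspath(path)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise MeshFormatError(f"output directory does not exist: {parent}")
    try:
        mesh.export(path, file_type="stl")
    except OSError as exc:
        raise MeshFormatError(f"could not write STL to {path}: {exc}") from exc


def is_watertight(mesh: TriMesh) -> bool:
    """Closed, consistently wound, and positively oriented."""
    if mesh is None or len(mesh.faces) == 0:
        return False
    return bool(
        mesh.is_watertight and mesh.is_winding_consistent and mesh.volume > 0
    )


def mesh_volume(mesh: TriMesh) -> float:
    """Signed-tetrahedron (divergence theorem) volume in mm^3.

    Raises :class:`WatertightError` for open meshes; an empty mesh (a legal
    boolean result) has volume 0.
    """
    if mesh is None or len(mesh.faces) == 0:
        return 0.0
    if not is_watertight(mesh):
        raise WatertightError(mesh.metadata.get("provenance", "mesh"))
    return float(mesh.volume)


def boundary_edges(mesh: TriMesh) -> np.ndarray:
    """Directed edges that appear in exactly one face, shape (n, 2)."""
    edges = mesh.edges  # directed, one per face corner
    undirected = np.sort(edges, axis=1)
    _, inverse, counts = np.unique(
        undirected, axis=0, return_inverse=True, return_counts=True
    )
    return edges[counts[inverse] == 1]


# ---------------------------------------------------------------------------
# watertight repair


def _assemble_loops(bedges: np.ndarray) -> list[np.ndarray]:
    """Order directed boundary edges into closed vertex loops.

    Returns [] if the boundary is non-manifold (a vertex with two outgoing
    boundary edges), in which case the caller falls back to unordered
    component filling.
    """
    nxt: dict[int, int] = {}
    for a, b in bedges:
        if int(a) in nxt:
            return []
        nxt[int(a)] = int(b)
    loops = []
    remaining = set(nxt)
    while remaining:
        start = min(remaining)
        loop = [start]
        remaining.discard(start)
        cur = nxt[start]
        while cur != start:
            if cur not in nxt or cur not in remaining:
                return []
            loop.append(cur)
            remaining.discard(cur)
            cur = nxt[cur]
        if len(loop) < 3:
            return []
        loops.append(np.array(loop, dtype=np.int64))
    return loops


def _earclip(points2d: np.ndarray, diag_ok=None) -> list[tuple[int, int, int]]:
    """Ear-clipping triangulation of a simple polygon (indices into the loop).

    Falls back to a fan if no ear is found (nearly degenerate loops from
    scan artifacts); the caller only needs a closed surface.
    """
    n = len(points2d)
    idx = list(range(n))
    # process CCW; if the input loop is CW, work on the reversal and flip
    # the emitted triangles back so they follow the input direction
    x, y = points2d[:, 0], points2d[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    flipped = area2 < 0
    if flipped:
        idx = idx[::-1]
    tris: list[tuple[int, int, int]] = []

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    guard = 0
    while len(idx) > 3 and guard < 10 * n:
        guard += 1
        m = len(idx)
        clipped = False
        for k in range(m):
            i0, i1, i2 = idx[k - 1], idx[k], idx[(k + 1) % m]
            p0, p1, p2 = points2d[i0], points2d[i1], points2d[i2]
            if cross(p0, p1, p2) <= 1e-14:
                continue  # reflex or degenerate corner
            if diag_ok is not None and not diag_ok(i0, i2):
                continue  # diagonal would collide with an existing edge
            # no other loop vertex inside the candidate ear
            ear_ok = True
            for j in idx:
                if j in (i0, i1, i2):
                    continue
                p = points2d[j]
                if (
                    cross(p0, p1, p) >= -1e-14
                    and cross(p1, p2, p) >= -1e-14
                    and cross(p2, p0, p) >= -1e-14
                ):
                    ear_ok = False
                    break
            if ear_ok:
                tris.append((i0, i1, i2))
                idx.pop(k)
                clipped = True
                break
        if not clipped:
            break
    if len(idx) == 3:
        tris.append((idx[0], idx[1], idx[2]))
    elif len(idx) > 3:  # stuck: centroid-free fan keeps the surface closed
        for k in range(1, len(idx) - 1):
            tris.append((idx[0], idx[k], idx[k + 1]))
    if flipped:
        tris = [(c, b, a) for a, b, c in tris]
    return tris


def _fill_loop(vertices: np.ndarray, loop: np.ndarray,
               forbidden: set | None = None) -> np.ndarray:
    """Triangulate one boundary loop by ear clipping in its best-fit plane.

    The loop is ordered along the *existing* boundary direction; the patch
    triangles are emitted reversed so each boundary edge ends up shared by
    exactly two faces with consistent winding.  ``forbidden`` holds
    undirected mesh edges the patch must not duplicate (a coinciding
    diagonal would create a 4-face edge).
    """
    pts = vertices[loop]
    centroid = pts.mean(axis=0)
    # best-fit plane basis via SVD
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    basis = vt[:2]
    p2 = (pts - centroid) @ basis.T
    diag_ok = None
    if forbidden:
        def diag_ok(a, c, _loop=loop, _forb=forbidden):
            return frozenset((int(_loop[a]), int(_loop[c]))) not in _forb
    local = _earclip(p2, diag_ok)
    # reverse each patch triangle to oppose the boundary direction
    return np.array(
        [(loop[a], loop[c], loop[b]) for a, b, c in local], dtype=np.int64
    ).reshape(-1, 3)


def repair_watertight(
    mesh: TriMesh,
    max_boundary_fraction: float = 0.05,
) -> TriMesh:
    """Close holes, fix winding/orientation, and validate watertightness.

    Procedure: deduplicate vertices and drop degenerate/duplicate faces;
    triangulate each boundary loop by ear clipping against the loop's
    best-fit plane; make winding consistent; flip to make the signed volume
    positive.  Idempotent on already-watertight meshes.

    ``max_boundary_fraction`` guards against inputs too damaged to be scan
    artifacts; a small absolute allowance (24 boundary edges) keeps tiny
    test meshes repairable regardless of their edge count.
    """
    if mesh is None or len(mesh.faces) == 0:
        raise RepairError("cannot repair an empty mesh")
    if mesh.is_watertight and mesh.is_winding_consistent:
        out = mesh.copy()
        if out.volume < 0:
            out.invert()
        return out
    verts, faces = _dedup(np.asarray(mesh.vertices), np.asarray(mesh.faces))
    if len(faces) == 0:
        raise RepairError("mesh has no non-degenerate triangles")
    work = make_mesh(verts, faces, mesh.metadata.get("provenance", "repaired"))

    # a vertex where two holes touch (two outgoing boundary edges) cannot be
    # filled manifold; widen the hole past the pinch by discarding its faces
    for _ in range(20):
        bedges = boundary_edges(work)
        if len(bedges) == 0:
            break
        starts, start_counts = np.unique(bedges[:, 0], return_counts=True)
        pinched = starts[start_counts > 1]
        if len(pinched) == 0:
            break
        keep = ~np.isin(work.faces, pinched).any(axis=1)
        verts, faces = _dedup(work.vertices, work.faces[keep])
        if len(faces) == 0:
            raise RepairError("mesh dissolved while resolving pinched holes")
        work = make_mesh(verts, faces, work.metadata.get("provenance", ""))

    bedges = boundary_edges(work)
    n_unique_edges = len(np.unique(np.sort(work.edges, axis=1), axis=0))
    if len(bedges) > max(max_boundary_fraction * n_unique_edges, 24):
        raise RepairError(
            f"{len(bedges)} boundary edges out of {n_unique_edges} "
            f"(> {max_boundary_fraction:.0%} and > 24); mesh too damaged"
        )

    if len(bedges):
        loops = _assemble_loops(bedges)
        patches = []
        extra_verts: list[np.ndarray] = []
        n_base = len(work.vertices)
        forbidden = {frozenset((int(a), int(b)))
                     for a, b in np.sort(work.edges, axis=1)}

        def _fan(loop_verts: np.ndarray, directed: np.ndarray):
            """Fan to a fresh apex vertex: collision-free by construction."""
            apex = n_base + len(extra_verts)
            extra_verts.append(work.vertices[loop_verts].mean(axis=0))
            return np.array([(b, a, apex) for a, b in directed],
                            dtype=np.int64)

        if loops:
            edge_by_start = {int(a): (int(a), int(b)) for a, b in bedges}
            for loop in loops:
                patch = _fill_loop(work.vertices, loop, forbidden)
                new_edges = {
                    frozenset((int(a), int(b)))
                    for tri in patch
                    for a, b in ((tri[0], tri[1]), (tri[1], tri[2]),
                                 (tri[2], tri[0]))
                    if frozenset((int(a), int(b))) not in forbidden
                }
                interior = {frozenset((int(loop[i]), int(loop[(i + 1) % len(loop)])))
                            for i in range(len(loop))}
                if any(e in forbidden and e not in interior for tri in patch
                       for e in (frozenset((int(tri[0]), int(tri[1]))),
                                 frozenset((int(tri[1]), int(tri[2]))),
                                 frozenset((int(tri[2]), int(tri[0]))))):
                    directed = np.array([edge_by_start[int(v)] for v in loop])
                    patch = _fan(np.unique(loop), directed)
                else:
                    forbidden.update(new_edges)
                patches.append(patch)
        else:
            # non-manifold boundary: one fan per connected boundary component
            comp = {}
            parent = {}

            def find(x):
                while parent.get(x, x) != x:
                    parent[x] = parent.get(parent[x], parent[x])
                    x = parent[x]
                return x

            for a, b in bedges:
                ra, rb = find(int(a)), find(int(b))
                if ra != rb:
                    parent[ra] = rb
            for a, b in bedges:
                comp.setdefault(find(int(a)), []).append((int(a), int(b)))
            for directed in comp.values():
                directed = np.array(directed, dtype=np.int64)
                patches.append(_fan(np.unique(directed), directed))

        verts = np.vstack([work.vertices, *extra_verts]) \
            if extra_verts else work.vertices
        faces = np.vstack([work.faces, *patches])
        work = make_mesh(verts, faces, work.metadata.get("provenance", ""))

    trimesh.repair.fix_normals(work)
    if work.volume < 0:
        work.invert()
    if not (work.is_watertight and work.is_winding_consistent):
        raise RepairError("repair failed: mesh is still open or inconsistent")
    if work.volume <= 1e-9:
        raise RepairError(
            "repair produced a degenerate (zero-volume) shell; "
            "input is irreparable"
        )
    work.metadata["provenance"] = mesh.metadata.get("provenance", "") or "repaired"
    return work
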