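"""Triangle-mesh container, file I/O and geometric utilities.

The whole pipeline works on plain triangular surface meshes of bone +
cartilage, assumed to be expressed in millimetres.  This module provides the
:class:`TriangleMesh` container together with the geometric primitives every
downstream stage relies on: per-vertex normals, edge-graph geodesic
neighborhoods, and closest-point-on-surface queries.

File parsing/serialisation (PLY, STL, OBJ; ASCII and binary variants) is
delegated to :mod:`trimesh`; this module only enforces the pipeline's
invariants on top (vertex welding, single connected component, no degenerate
faces).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import trimesh as _trimesh
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

__all__ = [
    "TriangleMesh",
    "VertexNeighborhood",
    "MeshFormatError",
    "MeshValidationError",
    "read_mesh",
    "write_mesh",
    "vertex_normals",
    "geodesic_neighborhood",
    "closest_point_on_surface",
]

_FORMATS = ("ply", "stl", "obj")
#: vertices closer than this (mm) are considered duplicates and welded on load
WELD_TOLERANCE = 1e-6


class MeshFormatError(ValueError):
    """A mesh file could not be parsed in the requested format."""


class MeshValidationError(ValueError):
    """A mesh violates the TriangleMesh invariants."""


@dataclasses.dataclass
class TriangleMesh:
    """A triangular surface mesh: ``vertices`` (n, 3) mm, ``faces`` (m, 3).

    Invariants (enforced by :meth:`validate`): all face indices valid, each
    face has three distinct vertices, and the mesh forms a single connected
    component.  Coordinates are treated as millimetres throughout; no unit
    conversion is attempted.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be an (m, 3) array")

    # -- invariants ---------------------------------------------------------
    def validate(self, require_connected: bool = True) -> "TriangleMesh":
        if len(self.vertices) == 0 or len(self.faces) == 0:
            raise MeshValidationError("empty mesh")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshValidationError("face index out of range")
        f = self.faces
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise MeshValidationError("degenerate face (repeated vertex index)")
        if require_connected:
            n_comp, _ = connected_components(self.vertex_adjacency, directed=False)
            if n_comp != 1:
                raise MeshValidationError(
                    f"mesh has {n_comp} connected components, expected 1"
                )
        return self

    # -- derived structure --------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) array with e0 < e1."""
        e = np.sort(
            np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]),
            axis=1,
        )
        return np.unique(e, axis=0)

    @property
    def vertex_adjacency(self) -> csr_matrix:
        """Sparse symmetric adjacency with Euclidean edge lengths as weights."""
        e = self.edges
        w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        n = self.n_vertices
        a = coo_matrix(
            (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(n, n),
        )
        return a.tocsr()

    def boundary_vertices(self) -> np.ndarray:
        """Boolean mask of vertices on an open boundary (edge with one face)."""
        e = np.sort(
            np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]),
            axis=1,
        )
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        mask = np.zeros(self.n_vertices, dtype=bool)
        mask[uniq[counts == 1].ravel()] = True
        return mask

    def face_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        v = self.vertices
        f = self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        norms = np.linalg.norm(cr, axis=1)
        areas = 0.5 * norms
        with np.errstate(invalid="ignore", divide="ignore"):
            normals = np.where(norms[:, None] > 0, cr / np.maximum(norms, 1e-300)[:, None], 0.0)
        return normals, areas

    def volume(self) -> float:
        """Signed enclosed volume (divergence theorem); meaningful for closed meshes."""
        v = self.vertices
        f = self.faces
        return float(np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0)

    def mean_edge_length(self) -> float:
        e = self.edges
        return float(np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1).mean())

    def copy(self, name: str | None = None) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), name if name is not None else self.name)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray, scale: float = 1.0) -> "TriangleMesh":
        """Apply ``x -> scale * R x + t`` to every vertex."""
        v = scale * self.vertices @ np.asarray(rotation).T + np.asarray(translation)
        return TriangleMesh(v, self.faces.copy(), self.name)

    # -- interop ------------------------------------------------------------
    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


@dataclasses.dataclass
class VertexNeighborhood:
    """Vertices within a geodesic ``radius`` (mm) of ``center`` on the edge graph."""

    center: int
    members: np.ndarray
    radius: float
    distances: np.ndarray

    def __contains__(self, idx: int) -> bool:
        return bool(np.isin(idx, self.members))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _weld(vertices: np.ndarray, faces: np.ndarray, tol: float = WELD_TOLERANCE):
    """Merge vertices closer than tol; lowest index wins. Drop degenerate faces."""
    if len(vertices) == 0:
        return vertices, faces
    tree = cKDTree(vertices)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    remap = np.arange(len(vertices))
    for a, b in pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]:
        ra, rb = remap[a], remap[b]
        lo, hi = (ra, rb) if ra < rb else (rb, ra)
        remap[remap == hi] = lo
    used = np.unique(remap)
    compact = np.full(len(vertices), -1, dtype=np.int64)
    compact[used] = np.arange(len(used))
    new_v = vertices[used]
    new_f = compact[remap[faces]]
    keep = (
        (new_f[:, 0] != new_f[:, 1])
        & (new_f[:, 1] != new_f[:, 2])
        & (new_f[:, 0] != new_f[:, 2])
    )
    return new_v, new_f[keep]


def _largest_component(vertices: np.ndarray, faces: np.ndarray):
    mesh = TriangleMesh(vertices, faces)
    n_comp, labels = connected_components(mesh.vertex_adjacency, directed=False)
    if n_comp == 1:
        return vertices, faces
    keep_label = np.bincount(labels).argmax()
    keep = labels == keep_label
    index = np.full(len(vertices), -1, dtype=np.int64)
    index[keep] = np.arange(int(keep.sum()))
    fmask = keep[faces].all(axis=1)
    return vertices[keep], index[faces[fmask]]


def read_mesh(path: str | Path, format: str | None = None) -> TriangleMesh:
    """Read a PLY/STL/OBJ surface mesh, weld duplicates and validate.

    STL stores no shared vertices, so welding always applies there; for PLY
    and OBJ only exact/near duplicates (within ``WELD_TOLERANCE`` mm) are
    merged.  If the file contains several connected components, the largest
    one is kept (clinical exports occasionally carry free-floating slivers).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = _trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise MeshFormatError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if raw.vertices is None or len(raw.vertices) == 0 or len(raw.faces) == 0:
        raise MeshValidationError(f"{path}: empty mesh")
    v, f = _weld(np.asarray(raw.vertices, dtype=np.float64), np.asarray(raw.faces, dtype=np.int64))
    v, f = _largest_component(v, f)
    return TriangleMesh(v, f, name=path.stem).validate()


def write_mesh(mesh: TriangleMesh, path: str | Path, format: str | None = None) -> None:
    """Write a mesh readable back by :func:`read_mesh` with identical topology."""
    mesh.validate()
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    mesh.to_trimesh().export(str(path), file_type=fmt)


# ---------------------------------------------------------------------------
# normals
# ---------------------------------------------------------------------------

def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Unit per-vertex normals: area-weighted average of incident face normals.

    Vertices without incident faces get a zero normal.
    """
    fn, areas = mesh.face_normals_areas()
    acc = np.zeros_like(mesh.vertices)
    w = fn * areas[:, None]
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], w)
    norms = np.linalg.norm(acc, axis=1)
    out = np.zeros_like(acc)
    nz = norms > 1e-300
    out[nz] = acc[nz] / norms[nz, None]
    return out


# ---------------------------------------------------------------------------
# geodesic neighborhoods (edge-graph shortest paths)
# ---------------------------------------------------------------------------

def geodesic_neighborhood(mesh: TriangleMesh, center: int, radius: float) -> VertexNeighborhood:
    """All vertices within edge-graph shortest-path distance ``radius`` of ``center``.

    Geodesic distance is approximated by Dijkstra over the edge graph with
    Euclidean edge weights; adequate for gating extremum searches, cheaper
    and simpler than exact polyhedral geodesics.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if not 0 <= center < mesh.n_vertices:
        raise IndexError(f"center {center} out of range [0, {mesh.n_vertices})")
    dist = dijkstra(mesh.vertex_adjacency, directed=False, indices=center, limit=radius)
    members = np.flatnonzero(np.isfinite(dist))
    return VertexNeighborhood(center=center, members=members, radius=radius, distances=dist[members])


# ---------------------------------------------------------------------------
# closest point on surface
# ---------------------------------------------------------------------------

class SurfaceProximity:
    """Closest-point-on-triangle queries against a fixed mesh.

    Candidate triangles come from a k-d tree over triangle centroids; the
    exact closest point is then computed on each candidate triangle and the
    best one kept.  ``k`` centroids per query is a heuristic: correct as long
    as the true closest triangle is among the k nearest centroids, which
    holds for the smooth, roughly-uniform meshes this pipeline produces.
    """

    def __init__(self, mesh: TriangleMesh, k: int = 12):
        self.mesh = mesh
        self.k = min(k, mesh.n_faces)
        self._tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
        self._tree = cKDTree(self._tri.mean(axis=1))
        self._boundary = mesh.boundary_vertices()
        self._face_touches_boundary = self._boundary[mesh.faces].any(axis=1)

    def query(self, points: np.ndarray):
        """Return (closest_points, distances, face_indices, barycentric)."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        _, cand = self._tree.query(points, k=self.k)
        cand = np.atleast_2d(cand)
        n, k = cand.shape
        tri = self._tri[cand.ravel()]  # (n*k, 3, 3)
        p = np.repeat(points, k, axis=0)
        cp, bary = _closest_point_triangle(p, tri)
        d = np.linalg.norm(cp - p, axis=1).reshape(n, k)
        best = d.argmin(axis=1)
        rows = np.arange(n)
        flat = rows * k + best
        return (
            cp[flat],
            d[rows, best],
            cand[rows, best],
            bary[flat],
        )

    def on_boundary(self, face_indices: np.ndarray) -> np.ndarray:
        """True where the hit triangle touches an open boundary of the mesh."""
        return self._face_touches_boundary[face_indices]


def _closest_point_triangle(p: np.ndarray, tri: np.ndarray):
    """Vectorised closest point on triangle (Ericson's method).

    Returns (closest_points (n,3), barycentric (n,3)).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp_ = p - c
    d5 = np.einsum("ij,ij->i", ab, cp_)
    d6 = np.einsum("ij,ij->i", ac, cp_)

    n = len(p)
    u = np.empty(n)
    v = np.empty(n)
    done = np.zeros(n, dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    u[m], v[m] = 0.0, 0.0
    done |= m
    m = ~done & (d3 >= 0) & (d4 <= d3)
    u[m], v[m] = 1.0, 0.0
    done |= m
    m = ~done & (d6 >= 0) & (d5 <= d6)
    u[m], v[m] = 0.0, 1.0
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = np.where(np.abs(d1 - d3) > 1e-300, d1 - d3, 1.0)
    u[m] = (d1 / denom)[m]
    v[m] = 0.0
    done |= m
    # edge AC
    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = np.where(np.abs(d2 - d6) > 1e-300, d2 - d6, 1.0)
    u[m] = 0.0
    v[m] = (d2 / denom)[m]
    done |= m
    # edge BC
    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    t = (d4 - d3) / np.where(np.abs((d4 - d3) + (d5 - d6)) > 1e-300, (d4 - d3) + (d5 - d6), 1.0)
    u[m] = (1.0 - t)[m]
    v[m] = t[m]
    done |= m

    # interior
    m = ~done
    denom = np.where(np.abs(va + vb + vc) > 1e-300, va + vb + vc, 1.0)
    u[m] = (vb / denom)[m]
    v[m] = (vc / denom)[m]

    w0 = 1.0 - u - v
    closest = a * w0[:, None] + b * u[:, None] + c * v[:, None]
    bary = np.stack([w0, u, v], axis=1)
    return closest, bary


def closest_point_on_surface(mesh: TriangleMesh, points: np.ndarray):
    """One-shot convenience wrapper around :class:`SurfaceProximity`."""
    return SurfaceProximity(mesh).query(points)
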