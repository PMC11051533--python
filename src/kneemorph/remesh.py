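"""Isotropic remeshing by the classic split / collapse / flip / smooth cycle.

Used to turn an arbitrary subject mesh into a well-conditioned template with
edge lengths concentrated near a chosen target.  The algorithm is the
standard incremental one: long edges are split at their midpoint, short
edges collapsed, edges flipped towards valence 6, and vertices tangentially
relaxed and re-projected onto the original surface so the shape is
preserved.  No exact output vertex count is guaranteed.
"""

from __future__ import annotations

import numpy as np

from .mesh import MeshValidationError, SurfaceProximity, TriangleMesh, vertex_normals

__all__ = ["isotropic_remesh"]

_MIN_FACES = 8  # refuse to degrade below a closed octahedron-sized mesh


class _EditableMesh:
    """Growable vertex/face store with incidence maps for local edits."""

    def __init__(self, mesh: TriangleMesh):
        self.verts: list[np.ndarray] = [v.copy() for v in mesh.vertices]
        self.faces: dict[int, tuple[int, int, int]] = {
            i: tuple(f) for i, f in enumerate(mesh.faces)
        }
        self._next_fid = len(self.faces)
        self.v2f: dict[int, set[int]] = {i: set() for i in range(len(self.verts))}
        for fid, f in self.faces.items():
            for v in f:
                self.v2f[v].add(fid)

    # -- queries ------------------------------------------------------------
    def edge_faces(self, a: int, b: int) -> list[int]:
        return [fid for fid in self.v2f[a] & self.v2f[b]]

    def neighbors(self, v: int) -> set[int]:
        out: set[int] = set()
        for fid in self.v2f[v]:
            out.update(self.faces[fid])
        out.discard(v)
        return out

    def is_boundary_vertex(self, v: int) -> bool:
        for nb in self.neighbors(v):
            if len(self.edge_faces(v, nb)) == 1:
                return True
        return False

    def edge_length(self, a: int, b: int) -> float:
        return float(np.linalg.norm(self.verts[a] - self.verts[b]))

    def all_edges(self) -> list[tuple[int, int]]:
        seen: set[tuple[int, int]] = set()
        for f in self.faces.values():
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                seen.add((a, b) if a < b else (b, a))
        return sorted(seen)

    # -- edits --------------------------------------------------------------
    def _add_face(self, f: tuple[int, int, int]) -> None:
        fid = self._next_fid
        self._next_fid += 1
        self.faces[fid] = f
        for v in f:
            self.v2f[v].add(fid)

    def _remove_face(self, fid: int) -> None:
        for v in self.faces[fid]:
            self.v2f[v].discard(fid)
        del self.faces[fid]

    def split_edge(self, a: int, b: int) -> int:
        """Insert the midpoint of (a, b), splitting each incident face in two."""
        mid = 0.5 * (self.verts[a] + self.verts[b])
        m = len(self.verts)
        self.verts.append(mid)
        self.v2f[m] = set()
        for fid in self.edge_faces(a, b):
            f = self.faces[fid]
            # rotate so the split edge is (f0, f1), keeping the winding
            for _ in range(3):
                if {f[0], f[1]} == {a, b}:
                    break
                f = (f[1], f[2], f[0])
            self._remove_face(fid)
            self._add_face((f[0], m, f[2]))
            self._add_face((m, f[1], f[2]))
        return m

    def collapse_edge(self, a: int, b: int) -> bool:
        """Collapse b into the midpoint of (a, b); False if illegal."""
        shared = self.edge_faces(a, b)
        if not shared:
            return False
        opposite = {v for fid in shared for v in self.faces[fid]} - {a, b}
        common = self.neighbors(a) & self.neighbors(b)
        if common != opposite:  # link condition: no pinched topology
            return False
        if len(self.faces) - len(shared) < _MIN_FACES:
            raise MeshValidationError(
                "target edge length too large: remeshing would degenerate the mesh"
            )
        self.verts[a] = 0.5 * (self.verts[a] + self.verts[b])
        for fid in shared:
            self._remove_face(fid)
        for fid in list(self.v2f[b]):
            f = self.faces[fid]
            self._remove_face(fid)
            self._add_face(tuple(a if v == b else v for v in f))
        del self.v2f[b]
        return True

    def flip_edge(self, a: int, b: int) -> bool:
        """Flip interior edge (a, b) to its opposite diagonal; False if illegal."""
        shared = self.edge_faces(a, b)
        if len(shared) != 2:
            return False
        f1, f2 = (self.faces[fid] for fid in shared)
        c = next(v for v in f1 if v not in (a, b))
        d = next(v for v in f2 if v not in (a, b))
        if c == d or d in self.neighbors(c):
            return False
        # orient from f1's winding: f1 cycles ... a -> b ... with c opposite
        for _ in range(3):
            if {f1[0], f1[1]} == {a, b}:
                break
            f1 = (f1[1], f1[2], f1[0])
        a0, b0 = f1[0], f1[1]
        for fid in shared:
            self._remove_face(fid)
        self._add_face((a0, d, c))
        self._add_face((d, b0, c))
        return True

    def to_mesh(self, name: str = "") -> TriangleMesh:
        keep = sorted(self.v2f.keys())
        index = {v: i for i, v in enumerate(keep)}
        verts = np.array([self.verts[v] for v in keep])
        faces = np.array([[index[v] for v in f] for f in self.faces.values()], dtype=np.int64)
        return TriangleMesh(verts, faces, name=name)


def _valence_gain(em: _EditableMesh, a: int, b: int, c: int, d: int) -> int:
    """Change in squared valence deviation if (a,b) flips to (c,d)."""

    def dev(v: int, delta: int) -> int:
        target = 4 if em.is_boundary_vertex(v) else 6
        val = len(em.neighbors(v))
        return (val + delta - target) ** 2 - (val - target) ** 2

    return dev(a, -1) + dev(b, -1) + dev(c, 1) + dev(d, 1)


def isotropic_remesh(
    mesh: TriangleMesh,
    target_edge_length: float,
    iterations: int = 5,
    smooth_lambda: float = 0.5,
) -> TriangleMesh:
    """Remesh towards uniform edge length ``target_edge_length`` (mm).

    The surface is preserved by re-projecting relaxed vertices onto the input
    mesh each iteration, so the geometric deviation stays well below the
    target edge length.  Boundary vertices of open meshes are kept fixed and
    never collapsed, preserving the field-of-view crop.
    """
    if target_edge_length <= 0:
        raise ValueError("target_edge_length must be > 0")
    mesh.validate()
    high = 4.0 / 3.0 * target_edge_length
    low = 4.0 / 5.0 * target_edge_length
    proximity = SurfaceProximity(mesh)
    em = _EditableMesh(mesh)

    for _ in range(iterations):
        # 1. split long edges (snapshot; new edges handled next iteration)
        for a, b in em.all_edges():
            if a in em.v2f and b in em.v2f and em.edge_length(a, b) > high:
                em.split_edge(a, b)
        # 2. collapse short edges
        for a, b in em.all_edges():
            if a not in em.v2f or b not in em.v2f:
                continue
            if b not in em.neighbors(a):
                continue
            if em.edge_length(a, b) >= low:
                continue
            if em.is_boundary_vertex(a) or em.is_boundary_vertex(b):
                continue
            mid = 0.5 * (em.verts[a] + em.verts[b])
            if any(
                np.linalg.norm(mid - em.verts[nb]) > high
                for nb in (em.neighbors(a) | em.neighbors(b)) - {a, b}
            ):
                continue
            em.collapse_edge(a, b)
        # 3. flip edges towards regular valence
        for a, b in em.all_edges():
            if a not in em.v2f or b not in em.v2f:
                continue
            shared = em.edge_faces(a, b)
            if len(shared) != 2:
                continue
            f1, f2 = (em.faces[fid] for fid in shared)
            c = next(v for v in f1 if v not in (a, b))
            d = next(v for v in f2 if v not in (a, b))
            if c == d:
                continue
            if _valence_gain(em, a, b, c, d) < 0:
                em.flip_edge(a, b)
        # 4. tangential smoothing + projection back onto the input surface
        current = em.to_mesh()
        normals = vertex_normals(current)
        keep_ids = sorted(em.v2f.keys())
        index = {v: i for i, v in enumerate(keep_ids)}
        boundary = current.boundary_vertices()
        new_pos = current.vertices.copy()
        for vid in keep_ids:
            i = index[vid]
            if boundary[i]:
                continue
            nbs = [em.verts[n] for n in em.neighbors(vid)]
            if not nbs:
                continue
            disp = np.mean(nbs, axis=0) - current.vertices[i]
            disp -= normals[i] * float(disp @ normals[i])  # tangential only
            new_pos[i] = current.vertices[i] + smooth_lambda * disp
        interior = ~boundary
        if interior.any():
            projected, _, _, _ = proximity.query(new_pos[interior])
            new_pos[interior] = projected
        for vid in keep_ids:
            em.verts[vid] = new_pos[index[vid]]

    out = em.to_mesh(name=mesh.name)
    out.validate()
    return out
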