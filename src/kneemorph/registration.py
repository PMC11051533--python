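"""Template-to-target surface registration.

A template bone mesh is aligned to each target in two stages:

1. **Rigid** iterative-closest-point alignment (point-to-surface).
2. **Constrained elastic** deformation: a per-vertex affine deformation
   field fitted by sparse least squares, with a graph-Laplacian stiffness
   term that is progressively relaxed (locally-affine nonrigid ICP).
   Correspondences are gated by distance and by surface-normal
   compatibility, and matches onto the open boundary of cropped targets are
   discarded so field-of-view edges do not drag the surface.

The deformed template carries the template topology, so vertex ``i`` refers
to the same anatomical location on every registered subject — a dense set of
corresponding pseudo-landmarks.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .mesh import SurfaceProximity, TriangleMesh, vertex_normals

__all__ = [
    "RigidTransform",
    "RegistrationConfig",
    "CorrespondedMesh",
    "DistortionReport",
    "RegistrationError",
    "rigid_align",
    "elastic_register",
    "mean_shape",
    "triangle_distortion",
]


class RegistrationError(RuntimeError):
    """Registration could not establish usable correspondences."""


@dataclasses.dataclass
class RigidTransform:
    """``x -> scale * R x + t`` with R a proper rotation."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-8 or not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation must be orthonormal with determinant +1")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.scale * other.translation @ self.rotation.T + self.translation,
            scale=self.scale * other.scale,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclasses.dataclass
class RegistrationConfig:
    """Tunable knobs shared by rigid and elastic registration.

    ``stiffness_schedule`` must be strictly decreasing: high stiffness first
    recovers a near-global deformation, later low values let local detail
    through.  ``normal_compat_threshold`` (degrees) rejects correspondences
    whose target normal disagrees with the template normal — the geometric
    constraint that keeps front and back surfaces from sticking together.
    """

    max_rigid_iters: int = 200
    elastic_steps: int = 8
    stiffness_schedule: tuple[float, ...] = (100.0, 50.0, 25.0, 12.5, 6.25, 3.125, 1.5625, 0.78125)
    normal_compat_threshold: float = 60.0
    max_corr_distance: float = 10.0
    convergence_tol: float = 0.01
    inner_iters: int = 3
    gamma: float = 1.0
    allow_scale: bool = False

    def __post_init__(self) -> None:
        sched = tuple(float(s) for s in self.stiffness_schedule)[: self.elastic_steps]
        if any(s <= 0 for s in sched):
            raise ValueError("stiffness_schedule entries must be > 0")
        if any(a <= b for a, b in zip(sched, sched[1:])):
            raise ValueError("stiffness_schedule must be strictly decreasing")
        self.stiffness_schedule = sched


@dataclasses.dataclass
class CorrespondedMesh:
    """A target surface re-expressed with the template's topology.

    ``vertices[i]`` is template vertex ``i`` deformed onto the target;
    ``residual[i]`` its remaining distance to the target surface (mm).
    """

    vertices: np.ndarray
    faces: np.ndarray
    source_target: str
    residual: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.residual = np.asarray(self.residual, dtype=np.float64)
        if len(self.residual) != len(self.vertices):
            raise ValueError("residual must have one entry per vertex")
        if np.any(self.residual < 0):
            raise ValueError("residuals must be non-negative")

    def as_mesh(self, name: str | None = None) -> TriangleMesh:
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), name or self.source_target)

    @classmethod
    def from_mesh(cls, mesh: TriangleMesh, source_target: str | None = None) -> "CorrespondedMesh":
        """Wrap a mesh as a trivially-corresponded instance of itself."""
        return cls(
            vertices=mesh.vertices.copy(),
            faces=mesh.faces.copy(),
            source_target=source_target or mesh.name,
            residual=np.zeros(mesh.n_vertices),
        )


@dataclasses.dataclass
class DistortionReport:
    """Per-triangle shape distortion of a deformed template.

    ``quality[t]`` is the condition number of the in-plane affine map from
    template triangle ``t`` to its deformed image: 1 when the triangle shape
    is preserved up to similarity, larger as it shears, infinite when the
    deformed triangle degenerates.
    """

    quality: np.ndarray
    threshold: float
    flagged_triangles: np.ndarray


# ---------------------------------------------------------------------------
# rigid ICP
# ---------------------------------------------------------------------------

def _kabsch(src: np.ndarray, dst: np.ndarray, allow_scale: bool) -> RigidTransform:
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    ps = src - mu_s
    pd = dst - mu_d
    h = ps.T @ pd
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    if allow_scale:
        scale = float((s * np.diag(flip)).sum() / (ps ** 2).sum())
    else:
        scale = 1.0
    t = mu_d - scale * rot @ mu_s
    return RigidTransform(rot, t, scale)


def rigid_align(
    source: TriangleMesh, target: TriangleMesh, config: RegistrationConfig | None = None
) -> RigidTransform:
    """ICP rigid alignment of ``source`` onto the surface of ``target``.

    Point-to-surface correspondences (closest point on target triangle) are
    gated at ``config.max_corr_distance``; each iteration solves the optimal
    rigid transform in closed form, so the mean squared distance is
    non-increasing.  Raises :class:`RegistrationError` when no vertex finds
    a correspondence — the meshes then need manual pre-alignment.
    """
    config = config or RegistrationConfig()
    if source.n_vertices == 0 or target.n_vertices == 0:
        raise RegistrationError("cannot align empty meshes")
    proximity = SurfaceProximity(target)
    transform = RigidTransform.identity()
    for _ in range(config.max_rigid_iters):
        moved = transform.apply(source.vertices)
        closest, dist, _, _ = proximity.query(moved)
        mask = dist <= config.max_corr_distance
        if not mask.any():
            raise RegistrationError(
                "no correspondences within max_corr_distance; pre-align the meshes"
            )
        new = _kabsch(source.vertices[mask], closest[mask], config.allow_scale)
        # stop when the transform stops moving the source (not on the
        # objective change, which flattens long before the pose settles)
        movement = float(np.abs(new.apply(source.vertices) - moved).max())
        transform = new
        if movement < 1e-3 * config.convergence_tol * max(1.0, float(np.abs(source.vertices).max())):
            break
    return transform


# ---------------------------------------------------------------------------
# elastic (locally-affine nonrigid ICP)
# ---------------------------------------------------------------------------

def _stiffness_matrix(mesh: TriangleMesh, gamma: float) -> sparse.csr_matrix:
    """Node-arc incidence kron diag(1,1,1,gamma): penalises affine differences."""
    edges = mesh.edges
    n = mesh.n_vertices
    e = len(edges)
    rows = np.repeat(np.arange(e), 2)
    cols = np.c_[edges[:, 0], edges[:, 1]].ravel()
    vals = np.tile([-1.0, 1.0], e)
    m = sparse.coo_matrix((vals, (rows, cols)), shape=(e, n)).tocsr()
    g = sparse.diags([1.0, 1.0, 1.0, gamma])
    return sparse.kron(m, g).tocsr()


def _data_matrix(vertices: np.ndarray) -> sparse.csr_matrix:
    """Block row ``[v_i 1]`` in column block i: evaluates the affine field."""
    n = len(vertices)
    rows = np.repeat(np.arange(n), 4)
    cols = (np.arange(n)[:, None] * 4 + np.arange(4)[None, :]).ravel()
    vals = np.c_[vertices, np.ones(n)].ravel()
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, 4 * n)).tocsr()


def elastic_register(
    template: TriangleMesh,
    target: TriangleMesh,
    config: RegistrationConfig | None = None,
) -> CorrespondedMesh:
    """Deform ``template`` onto ``target``, imposing the template topology.

    Per-vertex 3x4 affine transforms ``X_i`` are estimated by minimising

        alpha * || (M kron G) X ||^2  +  || W (D X - U) ||^2

    where ``M`` differences neighbouring transforms across edges (stiffness),
    ``D`` applies each transform to its vertex, and ``U`` holds the gated
    closest points on the target.  ``alpha`` is relaxed along the stiffness
    schedule; within each step correspondences and transforms alternate
    until the parameter change drops below ``convergence_tol``.
    """
    config = config or RegistrationConfig()
    template.validate()
    target.validate()

    rigid = rigid_align(template, target, config)
    current = rigid.apply(template.vertices)
    base = current.copy()

    proximity = SurfaceProximity(target)
    target_face_normals, _ = target.face_normals_areas()
    cos_thresh = float(np.cos(np.radians(config.normal_compat_threshold)))
    template_boundary = TriangleMesh(base, template.faces).boundary_vertices()

    n = template.n_vertices
    stiffness = _stiffness_matrix(template, config.gamma)
    d_mat = _data_matrix(base)

    # X stacked as (4n, 3); start at identity per vertex
    x = np.tile(np.vstack([np.eye(3), np.zeros(3)]), (n, 1))

    for alpha in config.stiffness_schedule:
        for _ in range(config.inner_iters):
            current = _apply_field(base, x)
            normals = vertex_normals(TriangleMesh(current, template.faces))
            closest, dist, hit_faces, _ = proximity.query(current)
            w = np.ones(n)
            w[dist > config.max_corr_distance] = 0.0
            compat = np.einsum("ij,ij->i", normals, target_face_normals[hit_faces])
            w[compat < cos_thresh] = 0.0
            w[proximity.on_boundary(hit_faces) & template_boundary] = 0.0
            if not w.any():
                raise RegistrationError("surfaces do not overlap: no usable correspondences")

            w_diag = sparse.diags(w)
            a = sparse.vstack([alpha * stiffness, w_diag @ d_mat]).tocsc()
            b = np.vstack([np.zeros((stiffness.shape[0], 3)), w[:, None] * closest])
            ata = (a.T @ a).tocsc()
            atb = a.T @ b
            x_new = np.column_stack([spsolve(ata, atb[:, k]) for k in range(3)])
            delta = float(np.abs(x_new - x).max())
            x = x_new
            if delta < config.convergence_tol:
                break

    final = _apply_field(base, x)
    _, residual, _, _ = proximity.query(final)
    frac_close = float(np.mean(residual <= config.max_corr_distance))
    if frac_close < 0.95:
        warnings.warn(
            f"elastic registration to {target.name!r} left {100 * (1 - frac_close):.1f}% "
            f"of vertices beyond {config.max_corr_distance} mm",
            RuntimeWarning,
            stacklevel=2,
        )
    return CorrespondedMesh(
        vertices=final,
        faces=template.faces.copy(),
        source_target=target.name,
        residual=residual,
    )


def _apply_field(base: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Evaluate the per-vertex affine field at its own vertex."""
    n = len(base)
    blocks = x.reshape(n, 4, 3)
    return np.einsum("nj,njk->nk", np.c_[base, np.ones(n)], blocks)


# ---------------------------------------------------------------------------
# mean shape & distortion
# ---------------------------------------------------------------------------

def mean_shape(corresponded: list[CorrespondedMesh], name: str = "mean_shape") -> TriangleMesh:
    """Vertex-wise arithmetic mean of topology-sharing corresponded meshes."""
    if not corresponded:
        raise ValueError("need at least one corresponded mesh")
    faces = corresponded[0].faces
    for cm in corresponded[1:]:
        if cm.faces.shape != faces.shape or not np.array_equal(cm.faces, faces):
            raise ValueError("corresponded meshes do not share the template topology")
    verts = np.mean([cm.vertices for cm in corresponded], axis=0)
    return TriangleMesh(verts, faces.copy(), name=name)


def triangle_distortion(
    deformed: CorrespondedMesh, template: TriangleMesh, threshold: float = 5.0
) -> DistortionReport:
    """Condition number of the in-plane affine map template tri -> deformed tri.

    Similarity-invariant: uniform scaling and rotation leave the metric at 1,
    shear and anisotropic stretch raise it.
    """
    if deformed.faces.shape != template.faces.shape or not np.array_equal(
        deformed.faces, template.faces
    ):
        raise ValueError("deformed mesh does not share the template topology")

    def _frames(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
        e1 = verts[faces[:, 1]] - verts[faces[:, 0]]
        e2 = verts[faces[:, 2]] - verts[faces[:, 0]]
        # orthonormal in-plane basis per triangle
        u = e1 / np.maximum(np.linalg.norm(e1, axis=1), 1e-300)[:, None]
        nrm = np.cross(e1, e2)
        nn = np.linalg.norm(nrm, axis=1)
        nrm = nrm / np.maximum(nn, 1e-300)[:, None]
        v = np.cross(nrm, u)
        # 2x2 edge matrix [e1 e2] in (u, v) coordinates
        out = np.empty((len(faces), 2, 2))
        out[:, 0, 0] = np.einsum("ij,ij->i", e1, u)
        out[:, 1, 0] = np.einsum("ij,ij->i", e1, v)
        out[:, 0, 1] = np.einsum("ij,ij->i", e2, u)
        out[:, 1, 1] = np.einsum("ij,ij->i", e2, v)
        return out

    src = _frames(template.vertices, template.faces)
    dst = _frames(deformed.vertices, deformed.faces)
    m = len(template.faces)
    quality = np.empty(m)
    dets = np.linalg.det(src)
    for t in range(m):
        if abs(dets[t]) < 1e-300:
            quality[t] = np.inf
            continue
        f = dst[t] @ np.linalg.inv(src[t])
        s = np.linalg.svd(f, compute_uv=False)
        quality[t] = np.inf if s[1] < 1e-12 else float(s[0] / s[1])
    flagged = np.flatnonzero(quality > threshold)
    return DistortionReport(quality=quality, threshold=threshold, flagged_triangles=flagged)
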