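"""Condyle-like synthetic phantoms with analytic ground-truth landmarks.

No clinical meshes ship with this package, so every pipeline stage is
exercised on stylised knee phantoms: star-shaped surfaces built from a base
ellipsoid plus smooth Gaussian radial lobes (condyles, trochlea, epicondyles,
intercondylar notch, tibial eminences), cropped by a shaft-cut plane to
emulate the limited scan field of view.

Ground truth is defined on the *continuous* analytic surface, independent of
any mesh: extremum-type landmarks are local optima of a frame coordinate
over the surface (found by deterministic local optimisation seeded at the
owning lobe's centre), constructed landmarks are fixed surface points, and
truth measurements are the axis projections of the truth landmarks.  The
lobes are shaped so that each extremum-type landmark has a genuine,
well-separated local extremum — the property the automated refinement step
relies on.

Inter-subject variation comes from smooth random radial-basis displacement
fields applied to mesh and analytic surface alike (truth extrema are
re-optimised on the deformed surface); observer annotations are emulated by
tangent-plane jitter re-projected onto the mesh.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import trimesh as _trimesh
from scipy.optimize import minimize

from .frames import AXIS_INDEX, ReferenceFrame, build_reference_frame, to_frame
from .landmarks import LandmarkDefinition, LandmarkSet, load_landmark_catalog
from .mesh import SurfaceProximity, TriangleMesh
from .morphometry import load_measurement_catalog, measure_all

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "KneePhantom",
    "generate_phantom",
    "generate_knee",
    "deform_phantom",
    "deform_knee",
    "simulate_observers",
]

#: proximal tibia is placed this far distal of the femur centre (mm)
TIBIA_OFFSET = np.array([0.0, 0.0, -70.0])


# ---------------------------------------------------------------------------
# analytic surface
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class _Bump:
    """Gaussian radial lobe: amplitude (mm) at ``direction``, angular sigma (rad)."""

    name: str
    direction: np.ndarray
    amplitude: float
    width: float


@dataclasses.dataclass
class RBFDisplacement:
    """Smooth vector field: sum of Gaussian kernels (centres mm, sigma mm)."""

    centers: np.ndarray  # (K, 3)
    vectors: np.ndarray  # (K, 3)
    sigma: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        d2 = ((points[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        w = np.exp(-0.5 * d2 / self.sigma ** 2)
        return w @ self.vectors


class PhantomSurface:
    """Star-shaped analytic surface: ellipsoid radius + Gaussian lobes,
    optionally composed with displacement fields."""

    def __init__(self, axes: tuple[float, float, float], bumps: list[_Bump],
                 center: np.ndarray | None = None):
        self.axes = np.asarray(axes, dtype=np.float64)
        self.bumps = bumps
        self.center = np.zeros(3) if center is None else np.asarray(center, dtype=np.float64)
        self.displacements: list[RBFDisplacement] = []

    def radius(self, u: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(u)
        base = 1.0 / np.sqrt(((u / self.axes) ** 2).sum(axis=1))
        r = base.copy()
        for b in self.bumps:
            cosang = np.clip(u @ b.direction, -1.0, 1.0)
            ang = np.arccos(cosang)
            r += b.amplitude * np.exp(-0.5 * (ang / b.width) ** 2)
        return r

    def point(self, u: np.ndarray) -> np.ndarray:
        """Surface point(s) for unit direction(s), displacement fields applied."""
        u = np.atleast_2d(u)
        p = self.radius(u)[:, None] * u + self.center
        for field in self.displacements:
            p = p + field(p)
        return p

    def copy(self) -> "PhantomSurface":
        out = PhantomSurface(tuple(self.axes), list(self.bumps), self.center.copy())
        out.displacements = list(self.displacements)
        return out


def _tangent_basis(u0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0]) if abs(u0[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    t1 = np.cross(u0, helper)
    t1 /= np.linalg.norm(t1)
    return t1, np.cross(u0, t1)


def _optimize_surface_extremum(
    surface: PhantomSurface,
    u0: np.ndarray,
    axis: str,
    sense: str,
    bound: float,
    strict: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Optimum of a coordinate over the surface within ``bound`` rad of u0.

    Optimises in a singularity-free tangent chart ``u(a, b) = normalize(u0 +
    a t1 + b t2)`` with bounded Nelder-Mead.  Bounding keeps the search
    inside the landmark's own lobe, exactly as the automated refinement
    bounds its geodesic search: the truth is "the most extreme point of this
    lobe's territory".  With ``strict`` (used when building the undeformed
    base phantom) an optimum pinned at the search boundary raises — the lobe
    then failed to realise the landmark as an interior local extremum.
    """
    from scipy.optimize import Bounds

    idx = AXIS_INDEX[axis]
    sign = -1.0 if sense == "max" else 1.0
    t1, t2 = _tangent_basis(u0)

    def objective(ab):
        u = u0 + ab[0] * t1 + ab[1] * t2
        u = u / np.linalg.norm(u)
        return sign * surface.point(u)[0, idx]

    # the chart coordinate |ab| = tan(angle); for the small bounds used here
    # the distinction from the angle itself is negligible
    res = minimize(objective, x0=[0.0, 0.0], method="Nelder-Mead",
                   bounds=Bounds(-bound, bound),
                   options={"xatol": 1e-7, "fatol": 1e-12, "maxiter": 800})
    if strict and np.max(np.abs(res.x)) > 0.95 * bound:
        raise RuntimeError(
            f"extremum pinned at the lobe boundary ({res.x}); landmark not realised"
        )
    u = u0 + res.x[0] * t1 + res.x[1] * t2
    u = u / np.linalg.norm(u)
    return surface.point(u)[0], u


# ---------------------------------------------------------------------------
# phantom specification and lobe tables
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one phantom bone.

    ``scale`` multiplies every length; ``mesh_resolution`` is the target
    edge length (mm) used to pick the sphere subdivision level;
    ``bump_scale`` globally scales lobe amplitudes; ``condyle_offsets``
    displaces named lobes (mm, converted to a direction perturbation);
    ``direction_jitter`` adds a deterministic random perturbation (radians
    SD, drawn from ``seed``) to every lobe direction, giving cheap
    per-seed shape variation.  Generation is deterministic given the spec.
    """

    bone: str = "femur_like"
    scale: float = 1.0
    mesh_resolution: float = 2.0
    bump_scale: float = 1.0
    condyle_offsets: dict[str, tuple[float, float, float]] = dataclasses.field(default_factory=dict)
    direction_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bone not in ("femur_like", "tibia_like"):
            raise ValueError("bone must be femur_like or tibia_like")
        if self.scale <= 0 or self.mesh_resolution <= 0:
            raise ValueError("scale and mesh_resolution must be > 0")
        if self.bump_scale < 0:
            raise ValueError("bump_scale must be >= 0")


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    return v / np.linalg.norm(v)


# (name, direction, amplitude mm, angular sigma rad)
_FEMUR_AXES = (40.0, 28.0, 30.0)
_FEMUR_CUT = 16.5  # keep z <= cut (distal part)
_FEMUR_BUMPS = [
    ("condyle_post_med", (-0.45, -0.85, -0.28), 10.0, 0.30),
    ("condyle_post_lat", (+0.45, -0.85, -0.28), 10.0, 0.30),
    ("condyle_dist_med", (-0.50, -0.20, -0.84), 9.0, 0.28),
    ("condyle_dist_lat", (+0.50, -0.20, -0.84), 9.0, 0.28),
    ("trochlea_ant_med", (-0.35, +0.85, -0.40), 9.0, 0.28),
    ("trochlea_ant_lat", (+0.35, +0.85, -0.40), 9.0, 0.28),
    ("epicondyle_med", (-0.93, +0.25, -0.26), 5.0, 0.28),
    ("epicondyle_lat", (+0.93, +0.25, -0.26), 5.0, 0.28),
    ("notch", (0.0, -0.88, -0.48), -16.0, 0.30),
    ("groove_dist", (0.0, -0.10, -0.99), -7.0, 0.25),
    ("groove_ant", (0.0, +0.78, -0.62), -9.0, 0.28),
]
#: extremum landmarks -> (seeding lobe, angular search bound rad); the bound
#: keeps the truth search inside the lobe's territory, well below the
#: angular separation to the nearest competing lobe of the same axis
_FEMUR_EXTREMA = {
    "FMCP": ("condyle_post_med", 0.45),
    "FLCP": ("condyle_post_lat", 0.45),
    "FMCD": ("condyle_dist_med", 0.45),
    "FLCD": ("condyle_dist_lat", 0.45),
    "FMTA": ("trochlea_ant_med", 0.40),
    "FLTA": ("trochlea_ant_lat", 0.40),
    "FME": ("epicondyle_med", 0.55),
    "FLE": ("epicondyle_lat", 0.55),
    "Notch": ("notch", 0.35),
}
_FEMUR_FIXED = {
    "FMCPP": (-0.50, -0.80, +0.33),
    "FLCPP": (+0.50, -0.80, +0.33),
    "FMCIP": (-0.20, -0.45, -0.87),
    "FMCEP": (-0.70, -0.40, -0.59),
    "FLCIP": (+0.20, -0.45, -0.87),
    "FLCEP": (+0.70, -0.40, -0.59),
}

_TIBIA_AXES = (38.0, 30.0, 28.0)
_TIBIA_CUT = -11.2  # keep z >= cut (proximal part)
_TIBIA_BUMPS = [
    ("eminence_med", (-0.22, 0.0, +0.97), 6.0, 0.14),
    ("eminence_lat", (+0.22, 0.0, +0.97), 6.0, 0.14),
    ("plateau_post_med", (-0.40, -0.89, +0.22), 8.0, 0.30),
    ("plateau_post_lat", (+0.40, -0.89, +0.22), 8.0, 0.30),
    ("plateau_med", (-0.97, -0.05, +0.24), 4.0, 0.30),
    ("plateau_lat", (+0.97, -0.05, +0.24), 4.0, 0.30),
    ("post_groove", (0.0, -0.95, +0.30), -5.0, 0.28),
]
_TIBIA_EXTREMA = {
    "TMIE": ("eminence_med", 0.18),
    "TLIE": ("eminence_lat", 0.18),
    "TMCP": ("plateau_post_med", 0.40),
    "TLCP": ("plateau_post_lat", 0.40),
    "TMCM": ("plateau_med", 0.55),
    "TLCL": ("plateau_lat", 0.55),
}
_TIBIA_FIXED = {
    "TMCA": (-0.45, +0.85, +0.28),
    "TLCA": (+0.45, +0.85, +0.28),
}


# ---------------------------------------------------------------------------
# truth container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PhantomTruth:
    """Analytic ground truth: landmark positions, frame and measurements.

    ``surfaces`` maps bone name -> analytic surface, ``charts`` maps landmark
    acronym -> (bone, unit direction) used to (re-)derive its truth position.
    """

    landmarks: dict[str, np.ndarray]
    frame: ReferenceFrame
    measurements: dict[str, float]
    surfaces: dict[str, PhantomSurface] = dataclasses.field(default_factory=dict, repr=False)
    #: acronym -> (bone, unit direction, angular search bound)
    charts: dict[str, tuple[str, np.ndarray, float]] = dataclasses.field(
        default_factory=dict, repr=False)

    def landmark_set(self, subject: str = "truth") -> LandmarkSet:
        return LandmarkSet(subject, "TRUTH", dict(self.landmarks), frame="RAW")


def _truth_measurements(landmarks: dict[str, np.ndarray], frame: ReferenceFrame) -> dict[str, float]:
    lset = LandmarkSet("truth", "TRUTH", dict(landmarks), frame="RAW")
    aligned = to_frame(lset, frame)
    catalog = [
        m for m in load_measurement_catalog()
        if {m.landmark_a, m.landmark_b} <= set(landmarks)
        and (m.alt_pair is None or set(m.alt_pair) <= set(landmarks))
    ]
    return {r.abbreviation: r.value for r in measure_all(aligned, catalog)}


def _truth_frame(landmarks: dict[str, np.ndarray]) -> ReferenceFrame:
    if "FMCP" in landmarks and "FLCP" in landmarks:
        return build_reference_frame(landmarks["FMCP"], landmarks["FLCP"])
    return ReferenceFrame.canonical()


def _solve_truth(
    surfaces: dict[str, PhantomSurface],
    charts: dict[str, tuple[str, np.ndarray, float]],
    catalog: dict[str, LandmarkDefinition],
    strict: bool = False,
) -> tuple[dict[str, np.ndarray], dict[str, tuple[str, np.ndarray, float]]]:
    """(Re-)derive truth landmarks from charts; extrema are re-optimised."""
    landmarks: dict[str, np.ndarray] = {}
    new_charts: dict[str, tuple[str, np.ndarray, float]] = {}
    for acr, (bone, u0, bound) in charts.items():
        d = catalog[acr]
        surface = surfaces[bone]
        if d.is_extremum:
            p, u = _optimize_surface_extremum(
                surface, u0, d.refine_axis, d.refine_sense, bound, strict=strict)
        else:
            p, u = surface.point(u0)[0], u0
        landmarks[acr] = p
        new_charts[acr] = (bone, u, bound)
    return landmarks, new_charts


# ---------------------------------------------------------------------------
# mesh synthesis
# ---------------------------------------------------------------------------

def _sphere_directions(resolution: float, mean_radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Icosphere tessellation fine enough for the requested edge length."""
    base_edge = 1.0514 * mean_radius  # icosahedron edge for unit circumradius
    subdivisions = max(2, round(math.log2(base_edge / resolution)))
    ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    return np.asarray(ico.vertices), np.asarray(ico.faces)


def _crop(vertices: np.ndarray, faces: np.ndarray, keep: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    index = np.full(len(vertices), -1, dtype=np.int64)
    index[keep] = np.arange(int(keep.sum()))
    fmask = keep[faces].all(axis=1)
    return vertices[keep], index[faces[fmask]]


def _build_surface(spec: PhantomSpec) -> tuple[PhantomSurface, dict, float]:
    femur = spec.bone == "femur_like"
    axes = np.array(_FEMUR_AXES if femur else _TIBIA_AXES) * spec.scale
    table = _FEMUR_BUMPS if femur else _TIBIA_BUMPS
    rng = np.random.default_rng(spec.seed)
    mean_radius = float(np.mean(axes))
    bumps = []
    for name, direction, amp, width in table:
        d = _unit(direction)
        if name in spec.condyle_offsets:
            d = _unit(d + np.asarray(spec.condyle_offsets[name]) / mean_radius)
        if spec.direction_jitter > 0:
            d = _unit(d + rng.normal(0.0, spec.direction_jitter, 3))
        bumps.append(_Bump(name, d, amp * spec.scale * spec.bump_scale, width))
    center = np.zeros(3) if femur else TIBIA_OFFSET * spec.scale
    surface = PhantomSurface(tuple(axes), bumps, center)
    cut = (_FEMUR_CUT if femur else _TIBIA_CUT) * spec.scale
    extrema = _FEMUR_EXTREMA if femur else _TIBIA_EXTREMA
    fixed = _FEMUR_FIXED if femur else _TIBIA_FIXED
    charts = {acr: (spec.bone, next(b.direction for b in bumps if b.name == lobe), bound)
              for acr, (lobe, bound) in extrema.items()}
    charts.update({acr: (spec.bone, _unit(d), 0.0) for acr, d in fixed.items()})
    return surface, charts, cut


def _mesh_surface(surface: PhantomSurface, spec: PhantomSpec, cut: float, name: str) -> TriangleMesh:
    mean_radius = float(np.mean(surface.axes))
    u, faces = _sphere_directions(spec.mesh_resolution, mean_radius)
    verts = surface.point(u)
    femur = spec.bone == "femur_like"
    rel = verts[:, 2] - surface.center[2]
    keep = rel <= cut if femur else rel >= cut
    verts, faces = _crop(verts, faces, keep)
    mesh = TriangleMesh(verts, faces, name=name)
    # the crop can strand tiny islands on the shaft side
    from .mesh import _largest_component  # local import to reuse the loader's cleanup

    v, f = _largest_component(mesh.vertices, mesh.faces)
    mesh = TriangleMesh(v, f, name=name).validate()
    min_width_mm = min(abs(b.width) * mean_radius for b in surface.bumps)
    if mesh.mean_edge_length() > min_width_mm:
        raise ValueError(
            f"mesh_resolution {spec.mesh_resolution} mm too coarse to resolve "
            f"bumps of angular footprint {min_width_mm:.1f} mm"
        )
    return mesh


def generate_phantom(spec: PhantomSpec) -> tuple[TriangleMesh, PhantomTruth]:
    """One phantom bone mesh plus its analytic ground truth."""
    surface, charts, cut = _build_surface(spec)
    catalog = load_landmark_catalog()
    mesh = _mesh_surface(surface, spec, cut, name=spec.bone)
    surfaces = {spec.bone: surface}
    landmarks, charts = _solve_truth(surfaces, charts, catalog, strict=True)
    frame = _truth_frame(landmarks)
    truth = PhantomTruth(
        landmarks=landmarks,
        frame=frame,
        measurements=_truth_measurements(landmarks, frame),
        surfaces=surfaces,
        charts=charts,
    )
    return mesh, truth


@dataclasses.dataclass
class KneePhantom:
    """A phantom knee: femur + tibia meshes sharing one ground truth."""

    subject: str
    femur: TriangleMesh
    tibia: TriangleMesh
    truth: PhantomTruth

    @property
    def meshes(self) -> dict[str, TriangleMesh]:
        return {"femur": self.femur, "tibia": self.tibia}


def generate_knee(
    subject: str = "phantom",
    scale: float = 1.0,
    mesh_resolution: float = 2.0,
    direction_jitter: float = 0.0,
    seed: int = 0,
) -> KneePhantom:
    """A femur + tibia phantom pair with the full 23-landmark ground truth."""
    fspec = PhantomSpec(bone="femur_like", scale=scale, mesh_resolution=mesh_resolution,
                        direction_jitter=direction_jitter, seed=seed)
    tspec = PhantomSpec(bone="tibia_like", scale=scale, mesh_resolution=mesh_resolution,
                        direction_jitter=direction_jitter, seed=seed + 1)
    femur_surface, femur_charts, fcut = _build_surface(fspec)
    tibia_surface, tibia_charts, tcut = _build_surface(tspec)
    femur_mesh = _mesh_surface(femur_surface, fspec, fcut, name=f"{subject}_femur")
    tibia_mesh = _mesh_surface(tibia_surface, tspec, tcut, name=f"{subject}_tibia")
    catalog = load_landmark_catalog()
    surfaces = {"femur_like": femur_surface, "tibia_like": tibia_surface}
    charts = {**femur_charts, **tibia_charts}
    landmarks, charts = _solve_truth(surfaces, charts, catalog, strict=True)
    frame = _truth_frame(landmarks)
    truth = PhantomTruth(
        landmarks=landmarks,
        frame=frame,
        measurements=_truth_measurements(landmarks, frame),
        surfaces=surfaces,
        charts=charts,
    )
    return KneePhantom(subject, femur_mesh, tibia_mesh, truth)


# ---------------------------------------------------------------------------
# smooth inter-subject deformation
# ---------------------------------------------------------------------------

def _make_field(
    rng: np.random.Generator, points: np.ndarray, magnitude: float, smoothness: float,
    n_kernels: int = 12,
) -> RBFDisplacement:
    lo = points.min(axis=0) - smoothness
    hi = points.max(axis=0) + smoothness
    centers = rng.uniform(lo, hi, size=(n_kernels, 3))
    vectors = rng.normal(0.0, 1.0, size=(n_kernels, 3))
    field = RBFDisplacement(centers, vectors, smoothness)
    rms = float(np.sqrt(np.mean(np.sum(field(points) ** 2, axis=1))))
    if rms < 1e-12:
        raise RuntimeError("degenerate displacement field")
    field.vectors = vectors * (magnitude / rms)
    return field


def _check_no_flips(before: TriangleMesh, after_vertices: np.ndarray) -> None:
    n0, _ = before.face_normals_areas()
    n1, _ = TriangleMesh(after_vertices, before.faces).face_normals_areas()
    if np.any(np.einsum("ij,ij->i", n0, n1) < 0):
        raise ValueError("deformation magnitude causes triangle flips (self-intersection)")


def deform_phantom(
    mesh: TriangleMesh,
    truth: PhantomTruth,
    magnitude: float,
    smoothness: float,
    seed: int,
    rigid_only: bool = False,
) -> tuple[TriangleMesh, PhantomTruth]:
    """Smoothly deform one phantom bone and its ground truth together.

    A band-limited Gaussian RBF displacement field (RMS amplitude
    ``magnitude`` mm, kernel sigma ``smoothness`` mm) moves the mesh
    vertices; truth extrema are re-optimised on the composed analytic
    surface and constructed landmarks follow the field.  ``rigid_only``
    applies a small random rotation + translation instead, which leaves all
    measurements unchanged (isometry).
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if not rigid_only and magnitude > 0 and smoothness < 3 * mesh.mean_edge_length():
        raise ValueError("smoothness must be >= 3x the mean edge length")
    catalog = load_landmark_catalog()
    rng = np.random.default_rng(seed)

    if rigid_only:
        angle = rng.normal(0.0, 0.05)
        axis = _unit(rng.normal(0.0, 1.0, 3))
        k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        rot = np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)
        t = rng.normal(0.0, magnitude if magnitude > 0 else 1.0, 3)
        new_mesh = mesh.transformed(rot, t)
        new_landmarks = {a: rot @ p + t for a, p in truth.landmarks.items()}
        # the scanner table axis rotates with the scan, keeping the frame
        # construction an isometry of the original
        if "FMCP" in new_landmarks and "FLCP" in new_landmarks:
            frame = build_reference_frame(new_landmarks["FMCP"], new_landmarks["FLCP"],
                                          table_axis=rot @ np.array([0.0, 0.0, 1.0]))
        else:
            frame = _truth_frame(new_landmarks)
        new_truth = PhantomTruth(new_landmarks, frame,
                                 _truth_measurements(new_landmarks, frame),
                                 truth.surfaces, truth.charts)
        return new_mesh, new_truth

    if magnitude == 0:
        return mesh.copy(), dataclasses.replace(truth)

    field = _make_field(rng, mesh.vertices, magnitude, smoothness)
    new_vertices = mesh.vertices + field(mesh.vertices)
    _check_no_flips(mesh, new_vertices)
    new_mesh = TriangleMesh(new_vertices, mesh.faces.copy(), name=mesh.name)

    surfaces = {bone: s.copy() for bone, s in truth.surfaces.items()}
    for s in surfaces.values():
        s.displacements = s.displacements + [field]
    landmarks, charts = _solve_truth(surfaces, truth.charts, catalog)
    frame = _truth_frame(landmarks)
    new_truth = PhantomTruth(landmarks, frame, _truth_measurements(landmarks, frame),
                             surfaces, charts)
    return new_mesh, new_truth


def deform_knee(knee: KneePhantom, magnitude: float, smoothness: float, seed: int,
                subject: str | None = None) -> KneePhantom:
    """Deform femur, tibia and truth of a knee phantom with one shared field."""
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    subject = subject or knee.subject
    if magnitude == 0:
        return KneePhantom(subject, knee.femur.copy(), knee.tibia.copy(),
                           dataclasses.replace(knee.truth))
    all_points = np.vstack([knee.femur.vertices, knee.tibia.vertices])
    min_edge = min(knee.femur.mean_edge_length(), knee.tibia.mean_edge_length())
    if smoothness < 3 * min_edge:
        raise ValueError("smoothness must be >= 3x the mean edge length")
    rng = np.random.default_rng(seed)
    field = _make_field(rng, all_points, magnitude, smoothness)

    new_meshes = {}
    for bone, mesh in knee.meshes.items():
        nv = mesh.vertices + field(mesh.vertices)
        _check_no_flips(mesh, nv)
        new_meshes[bone] = TriangleMesh(nv, mesh.faces.copy(), name=f"{subject}_{bone}")

    catalog = load_landmark_catalog()
    surfaces = {b: s.copy() for b, s in knee.truth.surfaces.items()}
    for s in surfaces.values():
        s.displacements = s.displacements + [field]
    landmarks, charts = _solve_truth(surfaces, knee.truth.charts, catalog)
    frame = _truth_frame(landmarks)
    truth = PhantomTruth(landmarks, frame, _truth_measurements(landmarks, frame),
                         surfaces, charts)
    return KneePhantom(subject, new_meshes["femur"], new_meshes["tibia"], truth)


# ---------------------------------------------------------------------------
# simulated observers
# ---------------------------------------------------------------------------

def simulate_observers(
    truth: PhantomTruth,
    meshes: dict[str, TriangleMesh],
    subject: str,
    n_observers: int = 3,
    n_repeats: int = 3,
    sigma_intra: float = 1.0,
    sigma_inter: float = 1.5,
    seed: int = 0,
) -> list[LandmarkSet]:
    """Emulated manual annotations: observer bias + repeat jitter, on-surface.

    Each observer draws a persistent tangent-plane bias per landmark (SD
    ``sigma_inter`` mm per component); observer 1 annotates ``n_repeats``
    times with additional tangent jitter (SD ``sigma_intra``), the others
    once.  All annotations are re-projected onto the bone mesh, matching how
    experts pick surface points.  Defaults mirror a three-observer design
    with one observer repeating three times and noise magnitudes of about
    1 mm (intra) and 1.5 mm (inter).
    """
    if sigma_intra < 0 or sigma_inter < 0:
        raise ValueError("sigmas must be >= 0")
    catalog = load_landmark_catalog()
    rng = np.random.default_rng(seed)
    prox = {bone: SurfaceProximity(mesh) for bone, mesh in meshes.items()}

    # tangent bases from the nearest mesh triangle normal at each landmark
    tangents: dict[str, tuple[str, np.ndarray, np.ndarray]] = {}
    for acr, p in truth.landmarks.items():
        bone = catalog[acr].bone
        _, _, face, _ = prox[bone].query(p)
        normals, _ = meshes[bone].face_normals_areas()
        n = normals[face[0]]
        t1, t2 = _tangent_basis(_unit(n))
        tangents[acr] = (bone, t1, t2)

    out: list[LandmarkSet] = []
    for obs_idx in range(n_observers):
        observer = f"obs{obs_idx + 1}"
        bias = {
            acr: rng.normal(0.0, sigma_inter) * t1 + rng.normal(0.0, sigma_inter) * t2
            for acr, (_, t1, t2) in tangents.items()
        }
        repeats = n_repeats if obs_idx == 0 else 1
        for _ in range(repeats):
            coords = {}
            for acr, p in truth.landmarks.items():
                bone, t1, t2 = tangents[acr]
                jitter = rng.normal(0.0, sigma_intra) * t1 + rng.normal(0.0, sigma_intra) * t2
                raw = p + bias[acr] + jitter
                projected, _, _, _ = prox[bone].query(raw)
                coords[acr] = projected[0]
            out.append(LandmarkSet(subject, observer, coords, frame="RAW"))
    return out
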