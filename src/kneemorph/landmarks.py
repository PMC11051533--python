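"""Named anatomical landmarks: catalog, propagation and extremum refinement.

The catalog (shipped as a JSON resource) names 23 landmarks on the distal
femur and proximal tibia.  Fifteen are defined as local surface extrema
("the most posterior point of the medial condyle", ...) and carry a
refinement axis and sense; the remaining eight are constructed definitions
tied to image views or notch-depth fractions and are propagated through the
dense correspondences without refinement.

Automated annotation works in three steps: a seed table maps each landmark
to a vertex of the mean shape; the correspondences transport that vertex
onto a subject; extremum-defined landmarks are then pushed to the locally
most extreme vertex along their axis within a geodesic search radius.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import AXIS_INDEX, ReferenceFrame
from .mesh import SurfaceProximity, TriangleMesh, geodesic_neighborhood
from .registration import CorrespondedMesh

__all__ = [
    "LandmarkDefinition",
    "LandmarkSet",
    "SeedTable",
    "load_landmark_catalog",
    "propagate_landmark",
    "expert_mean_landmarks",
    "build_seed_table",
    "optimize_extremum",
    "annotate_subject",
]

AUTO_OBSERVER = "AUTO"
#: landmarks farther than this (mm) from the source surface trigger a warning
PROPAGATION_DISTANCE_WARN = 5.0


@dataclasses.dataclass(frozen=True)
class LandmarkDefinition:
    """One catalog entry: acronym, owning bone and (optional) refinement rule."""

    acronym: str
    bone: str
    name: str
    description: str
    refine_axis: str | None = None
    refine_sense: str | None = None
    secondary_axis: str | None = None
    secondary_sense: str | None = None

    def __post_init__(self) -> None:
        if (self.refine_axis is None) != (self.refine_sense is None):
            raise ValueError(f"{self.acronym}: refine_axis and refine_sense must pair")
        if self.refine_axis is not None and self.refine_axis not in AXIS_INDEX:
            raise ValueError(f"{self.acronym}: bad refine_axis {self.refine_axis!r}")
        if self.refine_sense not in (None, "min", "max"):
            raise ValueError(f"{self.acronym}: bad refine_sense {self.refine_sense!r}")

    @property
    def is_extremum(self) -> bool:
        return self.refine_axis is not None


@dataclasses.dataclass
class LandmarkSet:
    """Concrete annotated coordinates for one subject by one observer."""

    subject: str
    observer: str
    coordinates: dict[str, np.ndarray]
    frame: str = "RAW"

    def __post_init__(self) -> None:
        self.coordinates = {
            k: np.asarray(v, dtype=np.float64) for k, v in self.coordinates.items()
        }
        for k, v in self.coordinates.items():
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"landmark {k}: coordinates must be a finite 3-vector")
        if self.frame not in ("RAW", "ALIGNED"):
            raise ValueError("frame must be RAW or ALIGNED")

    def __getitem__(self, acronym: str) -> np.ndarray:
        return self.coordinates[acronym]

    def acronyms(self) -> list[str]:
        return sorted(self.coordinates)

    def as_array(self, order: list[str] | None = None) -> np.ndarray:
        order = order or self.acronyms()
        return np.array([self.coordinates[a] for a in order])

    # -- serialisation ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "subject": self.subject,
            "observer": self.observer,
            "frame": self.frame,
            "landmarks": {k: list(map(float, v)) for k, v in self.coordinates.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            subject=payload["subject"],
            observer=payload["observer"],
            coordinates={k: np.asarray(v) for k, v in payload["landmarks"].items()},
            frame=payload.get("frame", "RAW"),
        )


def landmark_sets_to_csv(sets: list[LandmarkSet], path: str | Path) -> None:
    """Flat CSV: subject, observer, acronym, x, y, z."""
    rows = [
        {"subject": s.subject, "observer": s.observer, "acronym": a,
         "x": v[0], "y": v[1], "z": v[2]}
        for s in sets
        for a, v in sorted(s.coordinates.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def landmark_sets_from_csv(path: str | Path, frame: str = "RAW") -> list[LandmarkSet]:
    df = pd.read_csv(path)
    out = []
    for (subject, observer), grp in df.groupby(["subject", "observer"], sort=True):
        coords = {r.acronym: np.array([r.x, r.y, r.z]) for r in grp.itertuples()}
        out.append(LandmarkSet(str(subject), str(observer), coords, frame=frame))
    return out


@dataclasses.dataclass
class SeedTable:
    """Landmark acronym -> vertex index on the mean-shape topology."""

    indices: dict[str, int]

    def __getitem__(self, acronym: str) -> int:
        return self.indices[acronym]

    def validate_for(self, mesh: TriangleMesh) -> "SeedTable":
        for a, i in self.indices.items():
            if not 0 <= i < mesh.n_vertices:
                raise ValueError(f"seed for {a} ({i}) out of range for topology")
        return self


def load_landmark_catalog(path: str | Path | None = None) -> dict[str, LandmarkDefinition]:
    """Load the landmark catalog (the packaged one by default)."""
    if path is None:
        text = resources.files("kneemorph").joinpath("data/landmarks.json").read_text()
    else:
        text = Path(path).read_text()
    payload = json.loads(text)
    catalog: dict[str, LandmarkDefinition] = {}
    for entry in payload["landmarks"]:
        d = LandmarkDefinition(**{k: entry[k] for k in (
            "acronym", "bone", "name", "description",
            "refine_axis", "refine_sense", "secondary_axis", "secondary_sense")})
        if d.acronym in catalog:
            raise ValueError(f"duplicate acronym {d.acronym} in catalog")
        catalog[d.acronym] = d
    return catalog


# ---------------------------------------------------------------------------
# propagation through dense correspondences
# ---------------------------------------------------------------------------

def propagate_landmark(
    landmarks: LandmarkSet,
    source_corresponded: CorrespondedMesh,
    dest_corresponded: CorrespondedMesh,
) -> LandmarkSet:
    """Transport landmarks from one corresponded surface to another.

    Each landmark is expressed in barycentric coordinates of its nearest
    triangle on the source surface, then evaluated in the *same* triangle of
    the destination — triangles are in one-to-one correspondence because
    both meshes carry the template topology.
    """
    if source_corresponded.faces.shape != dest_corresponded.faces.shape or not np.array_equal(
        source_corresponded.faces, dest_corresponded.faces
    ):
        raise ValueError("source and destination do not share the template topology")
    src_mesh = source_corresponded.as_mesh()
    prox = SurfaceProximity(src_mesh)
    acronyms = landmarks.acronyms()
    points = landmarks.as_array(acronyms)
    _, dist, faces, bary = prox.query(points)
    far = dist > PROPAGATION_DISTANCE_WARN
    if far.any():
        names = [a for a, f in zip(acronyms, far) if f]
        warnings.warn(
            f"landmarks {names} are > {PROPAGATION_DISTANCE_WARN} mm from the source "
            "surface; projecting onto it first",
            RuntimeWarning,
            stacklevel=2,
        )
    tri = dest_corresponded.vertices[dest_corresponded.faces[faces]]  # (k, 3, 3)
    mapped = np.einsum("kj,kjd->kd", bary, tri)
    return LandmarkSet(
        subject=dest_corresponded.source_target,
        observer=landmarks.observer,
        coordinates=dict(zip(acronyms, mapped)),
        frame=landmarks.frame,
    )


def expert_mean_landmarks(observations: list[LandmarkSet]) -> LandmarkSet:
    """Equal-observer-weight mean: repeats of one observer averaged first.

    An observer with three repeats counts exactly as much as an observer with
    one; the returned set carries observer id ``"MEAN"``.
    """
    if not observations:
        raise ValueError("need at least one observation")
    subjects = {o.subject for o in observations}
    if len(subjects) != 1:
        raise ValueError(f"observations mix subjects: {sorted(subjects)}")
    frames = {o.frame for o in observations}
    if len(frames) != 1:
        raise ValueError("observations mix RAW and ALIGNED frames")
    all_acronyms = sorted(set().union(*(o.coordinates.keys() for o in observations)))
    by_observer: dict[str, list[LandmarkSet]] = {}
    for o in observations:
        by_observer.setdefault(o.observer, []).append(o)
    gaps = {
        obs: [a for a in all_acronyms if any(a not in s.coordinates for s in sets)]
        for obs, sets in by_observer.items()
    }
    gaps = {obs: missing for obs, missing in gaps.items() if missing}
    if gaps:
        raise ValueError(f"missing landmarks per observer: {gaps}")
    per_observer = [
        np.mean([s.as_array(all_acronyms) for s in sets], axis=0)
        for _, sets in sorted(by_observer.items())
    ]
    mean = np.mean(per_observer, axis=0)
    return LandmarkSet(
        subject=subjects.pop(),
        observer="MEAN",
        coordinates=dict(zip(all_acronyms, mean)),
        frame=frames.pop(),
    )


def build_seed_table(mean_shape: TriangleMesh, mean_landmarks: LandmarkSet) -> SeedTable:
    """Snap each mean landmark to its nearest mean-shape vertex.

    Exact nearest-vertex scan; ties resolved to the lowest index for
    determinism.
    """
    indices: dict[str, int] = {}
    for acronym in mean_landmarks.acronyms():
        d = np.linalg.norm(mean_shape.vertices - mean_landmarks[acronym], axis=1)
        if d.min() > PROPAGATION_DISTANCE_WARN:
            warnings.warn(
                f"landmark {acronym} is {d.min():.2f} mm from the mean shape",
                RuntimeWarning,
                stacklevel=2,
            )
        indices[acronym] = int(d.argmin())  # argmin returns the lowest tied index
    return SeedTable(indices)


# ---------------------------------------------------------------------------
# extremum refinement
# ---------------------------------------------------------------------------

def _scores(coords: np.ndarray, definition: LandmarkDefinition) -> tuple[np.ndarray, np.ndarray]:
    sign = 1.0 if definition.refine_sense == "max" else -1.0
    primary = sign * coords[:, AXIS_INDEX[definition.refine_axis]]
    if definition.secondary_axis is not None:
        s2 = 1.0 if definition.secondary_sense == "max" else -1.0
        secondary = s2 * coords[:, AXIS_INDEX[definition.secondary_axis]]
    else:
        secondary = np.zeros(len(coords))
    return primary, secondary


def optimize_extremum(
    mesh: TriangleMesh,
    seed_vertex: int,
    definition: LandmarkDefinition,
    frame: ReferenceFrame,
    search_radius: float = 10.0,
) -> int:
    """Most extreme vertex along the definition's axis near ``seed_vertex``.

    Candidates are the vertices within geodesic ``search_radius`` of the
    seed (edge-graph distance); the winner is the argmax/argmin of the frame
    coordinate along the refinement axis, with the secondary axis breaking
    exact primary ties and the lowest index breaking any remainder.  The
    result is then walked uphill along edges until no neighbour is more
    extreme, guaranteeing a local extremum even when the ball argmax sits on
    the search boundary.
    """
    if not definition.is_extremum:
        raise ValueError(f"{definition.acronym} is not an extremum-defined landmark")
    if not 0 <= seed_vertex < mesh.n_vertices:
        raise IndexError(f"seed vertex {seed_vertex} out of range")
    local = frame.to_local(mesh.vertices)
    primary, secondary = _scores(local, definition)

    nb = geodesic_neighborhood(mesh, seed_vertex, search_radius)
    members = nb.members
    # lexicographic argmax: primary, then secondary, then lowest index
    order = np.lexsort((members, -secondary[members], -primary[members]))
    best = int(members[order[0]])

    adjacency = mesh.vertex_adjacency
    while True:
        nbs = adjacency.indices[adjacency.indptr[best]: adjacency.indptr[best + 1]]
        better = nbs[
            (primary[nbs] > primary[best])
            | ((primary[nbs] == primary[best]) & (secondary[nbs] > secondary[best]))
        ]
        if len(better) == 0:
            return best
        order = np.lexsort((better, -secondary[better], -primary[better]))
        best = int(better[order[0]])


@dataclasses.dataclass
class AnnotationConfig:
    """Knobs for automated annotation (geodesic search radius in mm)."""

    search_radius: float = 10.0


def annotate_subject(
    subject_corresponded: CorrespondedMesh,
    seeds: SeedTable,
    catalog: dict[str, LandmarkDefinition] | list[LandmarkDefinition],
    frame: ReferenceFrame,
    config: AnnotationConfig | None = None,
) -> LandmarkSet:
    """Automated landmark set for one subject from its corresponded mesh.

    Seed vertices are transported by index (the whole point of imposing the
    template topology), then extremum-defined landmarks are refined with
    :func:`optimize_extremum`.  Every output coordinate is a vertex of the
    subject's corresponded mesh; the observer id is ``AUTO``.
    """
    config = config or AnnotationConfig()
    if isinstance(catalog, list):
        catalog = {d.acronym: d for d in catalog}
    mesh = subject_corresponded.as_mesh()
    seeds.validate_for(mesh)
    coords: dict[str, np.ndarray] = {}
    for acronym, definition in catalog.items():
        if acronym not in seeds.indices:
            raise KeyError(f"no seed for landmark {acronym}")
        vertex = seeds[acronym]
        if definition.is_extremum:
            vertex = optimize_extremum(mesh, vertex, definition, frame, config.search_radius)
        coords[acronym] = mesh.vertices[vertex].copy()
    return LandmarkSet(
        subject=subject_corresponded.source_target,
        observer=AUTO_OBSERVER,
        coordinates=coords,
        frame="RAW",
    )
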