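"""Axis-projection morphometric measurements of the knee.

Each measurement is the absolute difference of two landmarks' coordinates
along one axis of the posterior-condylar-line reference frame — e.g. the
anteroposterior size of the medial femoral condyle is |y(FMCP) - y(FMTA)|.
The packaged catalog defines the 15 standard femoral/tibial compartment
sizes; the notch AP size averages its medial and lateral condyle variants.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import AXIS_INDEX
from .landmarks import LandmarkSet

__all__ = [
    "MeasurementDefinition",
    "MeasurementResult",
    "load_measurement_catalog",
    "compute_measurement",
    "measure_all",
]


@dataclasses.dataclass(frozen=True)
class MeasurementDefinition:
    """Two landmarks and the frame axis their difference is projected on."""

    abbreviation: str
    description: str
    landmark_a: str
    landmark_b: str
    axis: str
    alt_pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.axis not in AXIS_INDEX:
            raise ValueError(f"{self.abbreviation}: axis must be one of x/y/z")


@dataclasses.dataclass
class MeasurementResult:
    abbreviation: str
    subject: str
    observer: str
    value: float
    components: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("measurement values are absolute differences, >= 0")


def load_measurement_catalog(path: str | Path | None = None) -> list[MeasurementDefinition]:
    if path is None:
        text = resources.files("kneemorph").joinpath("data/measurements.json").read_text()
    else:
        text = Path(path).read_text()
    payload = json.loads(text)
    out = []
    for e in payload["measurements"]:
        alt = tuple(e["alt_pair"]) if e.get("alt_pair") else None
        out.append(
            MeasurementDefinition(
                abbreviation=e["abbreviation"],
                description=e["description"],
                landmark_a=e["landmark_a"],
                landmark_b=e["landmark_b"],
                axis=e["axis"],
                alt_pair=alt,
            )
        )
    return out


def _projection(landmarks: LandmarkSet, a: str, b: str, axis: str) -> float:
    for acronym in (a, b):
        if acronym not in landmarks.coordinates:
            raise KeyError(f"landmark {acronym} missing from set for {landmarks.subject}")
    i = AXIS_INDEX[axis]
    return float(abs(landmarks[a][i] - landmarks[b][i]))


def compute_measurement(
    definition: MeasurementDefinition, landmarks: LandmarkSet
) -> MeasurementResult:
    """Evaluate one measurement on an ALIGNED landmark set.

    RAW input is rejected: projections are only meaningful once the
    condylar line has been rotated parallel to the mediolateral axis.
    When an alternate landmark pair exists (notch AP size), the value is
    the mean of both pair projections and the components are kept.
    """
    if landmarks.frame != "ALIGNED":
        raise ValueError(
            f"{definition.abbreviation}: landmark set must be ALIGNED to the "
            "reference frame before measuring"
        )
    v1 = _projection(landmarks, definition.landmark_a, definition.landmark_b, definition.axis)
    if definition.alt_pair is None:
        return MeasurementResult(definition.abbreviation, landmarks.subject, landmarks.observer, v1)
    v2 = _projection(landmarks, *definition.alt_pair, definition.axis)
    return MeasurementResult(
        definition.abbreviation,
        landmarks.subject,
        landmarks.observer,
        value=0.5 * (v1 + v2),
        components=(v1, v2),
    )


def measure_all(
    landmarks: LandmarkSet, catalog: list[MeasurementDefinition] | None = None
) -> list[MeasurementResult]:
    """All catalog measurements for one ALIGNED landmark set."""
    catalog = catalog if catalog is not None else load_measurement_catalog()
    results = []
    for definition in catalog:
        try:
            results.append(compute_measurement(definition, landmarks))
        except KeyError as exc:
            raise KeyError(f"{definition.abbreviation}: {exc}") from exc
    return results


def measurements_to_csv(results: list[MeasurementResult], path: str | Path) -> None:
    rows = [
        {"subject": r.subject, "observer": r.observer,
         "abbreviation": r.abbreviation, "value_mm": r.value}
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def measurements_to_json(results: list[MeasurementResult], path: str | Path) -> None:
    payload = [
        {"subject": r.subject, "observer": r.observer,
         "abbreviation": r.abbreviation, "value_mm": r.value}
        for r in results
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def measurements_from_csv(path: str | Path) -> list[MeasurementResult]:
    df = pd.read_csv(path)
    return [
        MeasurementResult(r.abbreviation, str(r.subject), str(r.observer), float(r.value_mm))
        for r in df.itertuples()
    ]
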