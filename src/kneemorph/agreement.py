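"""Agreement statistics for landmark positions and morphometric measurements.

Three comparisons are supported, each with its own ground-truth rule:

* ``INTRA`` — repeated annotations by one observer, against the mean of the
  repeats;
* ``INTER`` — one (repeat-averaged) annotation per observer, against the
  equal-weight expert mean;
* ``METHOD`` — the automated annotation against the expert mean.

Landmark errors are Euclidean distances; measurement errors are absolute
scalar differences.  Summaries follow the standard descriptive toolkit:
quartiles with the 1.5*IQR outlier rule, mean +/- SD, intraclass
correlation (two-way ANOVA, absolute agreement, single rater), Bland-Altman
limits of agreement, and success-rate-at-tolerance curves (the empirical
CDF of errors).
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict

import numpy as np
import pandas as pd

from .landmarks import AUTO_OBSERVER, LandmarkSet
from .morphometry import MeasurementResult

__all__ = [
    "ErrorSample",
    "QuartileSummary",
    "ICCResult",
    "BlandAltman",
    "SuccessCurve",
    "landmark_errors",
    "measurement_errors",
    "quartile_summary",
    "icc",
    "bland_altman",
    "success_rates",
    "outliers_per_subject",
]

MODES = ("INTRA", "INTER", "METHOD")


@dataclasses.dataclass(frozen=True)
class ErrorSample:
    """One observation's deviation from its mode's ground truth (mm)."""

    subject: str
    item: str  # landmark acronym or measurement abbreviation
    comparison: str  # INTRA | INTER | METHOD
    error: float
    observer: str = ""

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError("errors are distances/absolute differences, >= 0")
        if self.comparison not in MODES:
            raise ValueError(f"comparison must be one of {MODES}")


# ---------------------------------------------------------------------------
# error extraction
# ---------------------------------------------------------------------------

def _per_observer_means(sets: list[LandmarkSet]) -> dict[str, dict[str, np.ndarray]]:
    """Average each observer's repeats, acronym-wise."""
    grouped: dict[str, list[LandmarkSet]] = defaultdict(list)
    for s in sets:
        grouped[s.observer].append(s)
    out = {}
    for obs, repeats in grouped.items():
        acronyms = sorted(set().union(*(r.coordinates.keys() for r in repeats)))
        out[obs] = {
            a: np.mean([r[a] for r in repeats if a in r.coordinates], axis=0)
            for a in acronyms
        }
    return out


def landmark_errors(observations: list[LandmarkSet], mode: str) -> list[ErrorSample]:
    """Euclidean landmark errors against the mode's ground truth.

    INTRA expects >= 2 repeats of a single observer per subject.  INTER
    expects >= 2 observers (repeats are pre-averaged so each observer
    weighs equally).  METHOD expects manual observers plus one ``AUTO`` set
    per subject; the ground truth is the expert mean of the manual sets.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    by_subject: dict[str, list[LandmarkSet]] = defaultdict(list)
    for s in observations:
        by_subject[s.subject].append(s)
    samples: list[ErrorSample] = []
    for subject, sets in sorted(by_subject.items()):
        manual = [s for s in sets if s.observer != AUTO_OBSERVER]
        auto = [s for s in sets if s.observer == AUTO_OBSERVER]
        if mode == "INTRA":
            observers = {s.observer for s in manual}
            if len(observers) != 1 or len(manual) < 2:
                raise ValueError(
                    f"{subject}: INTRA needs >=2 repeats of one observer, "
                    f"got {len(manual)} sets from {sorted(observers)}"
                )
            acronyms = sorted(manual[0].coordinates)
            gt = {a: np.mean([s[a] for s in manual], axis=0) for a in acronyms}
            for s in manual:
                for a in acronyms:
                    samples.append(ErrorSample(
                        subject, a, mode, float(np.linalg.norm(s[a] - gt[a])), s.observer))
        elif mode == "INTER":
            means = _per_observer_means(manual)
            if len(means) < 2:
                raise ValueError(f"{subject}: INTER needs >=2 observers")
            acronyms = sorted(next(iter(means.values())))
            gt = {a: np.mean([m[a] for m in means.values()], axis=0) for a in acronyms}
            for obs, m in sorted(means.items()):
                for a in acronyms:
                    samples.append(ErrorSample(
                        subject, a, mode, float(np.linalg.norm(m[a] - gt[a])), obs))
        else:  # METHOD
            if len(auto) != 1:
                raise ValueError(f"{subject}: METHOD needs exactly one AUTO set")
            means = _per_observer_means(manual)
            if not means:
                raise ValueError(f"{subject}: METHOD needs manual observations")
            acronyms = sorted(next(iter(means.values())))
            gt = {a: np.mean([m[a] for m in means.values()], axis=0) for a in acronyms}
            for a in acronyms:
                samples.append(ErrorSample(
                    subject, a, mode, float(np.linalg.norm(auto[0][a] - gt[a])), AUTO_OBSERVER))
    return samples


def measurement_errors(measurements: list[MeasurementResult], mode: str) -> list[ErrorSample]:
    """Absolute measurement differences against the mode's ground truth.

    Same grouping rules as :func:`landmark_errors`, with scalar values.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    grouped: dict[tuple[str, str], list[MeasurementResult]] = defaultdict(list)
    for r in measurements:
        grouped[(r.subject, r.abbreviation)].append(r)
    samples: list[ErrorSample] = []
    for (subject, item), results in sorted(grouped.items()):
        manual = [r for r in results if r.observer != AUTO_OBSERVER]
        auto = [r for r in results if r.observer == AUTO_OBSERVER]
        if mode == "INTRA":
            observers = {r.observer for r in manual}
            if len(observers) != 1 or len(manual) < 2:
                raise ValueError(f"{subject}/{item}: INTRA needs >=2 repeats of one observer")
            gt = float(np.mean([r.value for r in manual]))
            for r in manual:
                samples.append(ErrorSample(subject, item, mode, abs(r.value - gt), r.observer))
        elif mode == "INTER":
            per_obs: dict[str, list[float]] = defaultdict(list)
            for r in manual:
                per_obs[r.observer].append(r.value)
            if len(per_obs) < 2:
                raise ValueError(f"{subject}/{item}: INTER needs >=2 observers")
            means = {obs: float(np.mean(v)) for obs, v in per_obs.items()}
            gt = float(np.mean(list(means.values())))
            for obs, v in sorted(means.items()):
                samples.append(ErrorSample(subject, item, mode, abs(v - gt), obs))
        else:  # METHOD
            if len(auto) != 1:
                raise ValueError(f"{subject}/{item}: METHOD needs exactly one AUTO value")
            per_obs = defaultdict(list)
            for r in manual:
                per_obs[r.observer].append(r.value)
            if not per_obs:
                raise ValueError(f"{subject}/{item}: METHOD needs manual values")
            gt = float(np.mean([np.mean(v) for _, v in sorted(per_obs.items())]))
            samples.append(
                ErrorSample(subject, item, mode, abs(auto[0].value - gt), AUTO_OBSERVER))
    return samples


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class QuartileSummary:
    """Quartiles, 1.5*IQR outlier thresholds and mean +/- SD of errors."""

    q1: float
    median: float
    q3: float
    iqr: float
    outlier_low: float
    outlier_high: float
    outlier_ids: list[ErrorSample]
    mean: float
    sd: float
    n: int


def quartile_summary(samples: list[ErrorSample]) -> QuartileSummary:
    """Summarise error samples; quartiles by linear interpolation (type 7).

    Observations outside ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`` are flagged as
    outliers.  SD is the sample standard deviation (ddof=1; 0 for n=1).
    """
    if not samples:
        raise ValueError("no samples")
    errors = np.array([s.error for s in samples])
    q1, median, q3 = np.percentile(errors, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flagged = [s for s in samples if s.error < lo or s.error > hi]
    sd = float(errors.std(ddof=1)) if len(errors) > 1 else 0.0
    return QuartileSummary(
        q1=float(q1), median=float(median), q3=float(q3), iqr=float(iqr),
        outlier_low=float(lo), outlier_high=float(hi), outlier_ids=flagged,
        mean=float(errors.mean()), sd=sd, n=len(errors),
    )


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ICCResult:
    """Absolute-agreement single-rater ICC from a two-way ANOVA.

    The point estimate is identical for the two-way mixed and two-way random
    models under absolute agreement; ``model`` records which interpretation
    applies (mixed for repeats of one observer, random for a sample of
    observers or methods).
    """

    model: str  # TWO_WAY_MIXED | TWO_WAY_RANDOM
    definition: str
    unit: str
    value: float
    n_subjects: int
    n_raters: int
    degenerate: bool = False


def icc(table: np.ndarray, model: str = "TWO_WAY_RANDOM") -> ICCResult:
    """ICC(A,1): two-way ANOVA, absolute agreement, single rater/measurement.

    ``table`` is subjects x raters with no missing cells.  From the mean
    squares for rows (subjects), columns (raters) and error::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    A table whose cells are all equal has no variance to apportion; it is
    reported as ICC 1 with ``degenerate=True``.
    """
    if model not in ("TWO_WAY_MIXED", "TWO_WAY_RANDOM"):
        raise ValueError("model must be TWO_WAY_MIXED or TWO_WAY_RANDOM")
    table = np.asarray(table, dtype=np.float64)
    if table.ndim != 2:
        raise ValueError("table must be 2-D (subjects x raters)")
    n, k = table.shape
    if n < 2 or k < 2:
        raise ValueError("need >=2 subjects and >=2 raters")
    if not np.all(np.isfinite(table)):
        raise ValueError("table has missing/non-finite cells")

    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if np.isclose(denom, 0.0, atol=1e-30):
        return ICCResult(model, "ABSOLUTE_AGREEMENT", "SINGLE_RATER", 1.0, n, k, degenerate=True)
    value = float((msr - mse) / denom)
    return ICCResult(model, "ABSOLUTE_AGREEMENT", "SINGLE_RATER", value, n, k)


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BlandAltman:
    """Bias and 95% limits of agreement between two methods."""

    means: np.ndarray  # per-subject mean of the pair
    differences: np.ndarray  # per-subject (second - first)
    bias: float
    loa_low: float
    loa_high: float


def bland_altman(first: np.ndarray, second: np.ndarray) -> BlandAltman:
    """Limits of agreement for paired values (e.g. manual mean vs automated).

    ``bias = mean(second - first)``; limits are ``bias +/- 1.96 * SD`` of
    the differences (sample SD).
    """
    first = np.asarray(first, dtype=np.float64)
    second = np.asarray(second, dtype=np.float64)
    if first.shape != second.shape or first.ndim != 1:
        raise ValueError("first and second must be 1-D arrays of equal length")
    if len(first) < 2:
        raise ValueError("need >=2 pairs")
    diff = second - first
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltman(
        means=0.5 * (first + second),
        differences=diff,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


# ---------------------------------------------------------------------------
# success curves and outlier bookkeeping
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SuccessCurve:
    """Fraction of errors within each tolerance — the empirical CDF."""

    item: str
    tolerances: np.ndarray
    rates: np.ndarray


def success_rates(
    samples: list[ErrorSample], tolerances: np.ndarray, item: str = "all"
) -> SuccessCurve:
    """Success rate (fraction with error <= tolerance) on a tolerance grid."""
    if not samples:
        raise ValueError("no samples")
    tolerances = np.asarray(tolerances, dtype=np.float64)
    if np.any(tolerances <= 0):
        raise ValueError("tolerances must be > 0")
    errors = np.array([s.error for s in samples])
    rates = np.array([float(np.mean(errors <= t)) for t in tolerances])
    return SuccessCurve(item=item, tolerances=tolerances, rates=rates)


def outliers_per_subject(samples: list[ErrorSample]) -> dict[tuple[str, str], int]:
    """Count 1.5*IQR outliers per (subject, comparison), item-wise thresholds.

    Thresholds are computed per item (landmark or measurement) within each
    comparison mode, mirroring how the per-item summaries flag outliers.
    """
    by_item: dict[tuple[str, str], list[ErrorSample]] = defaultdict(list)
    for s in samples:
        by_item[(s.comparison, s.item)].append(s)
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for s in samples:  # zero-initialise every subject/mode pair present
        counts[(s.subject, s.comparison)] += 0
    for (_, _), group in by_item.items():
        summary = quartile_summary(group)
        for s in summary.outlier_ids:
            counts[(s.subject, s.comparison)] += 1
    return dict(counts)


def summaries_to_frame(groups: dict[str, list[ErrorSample]]) -> pd.DataFrame:
    """Tidy per-item summary table (one row per item)."""
    rows = []
    for item, samples in sorted(groups.items()):
        s = quartile_summary(samples)
        rows.append({
            "item": item, "comparison": samples[0].comparison, "n": s.n,
            "q1": s.q1, "median": s.median, "q3": s.q3,
            "mean": s.mean, "sd": s.sd, "n_outliers": len(s.outlier_ids),
        })
    return pd.DataFrame(rows)
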