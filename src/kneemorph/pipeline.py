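"""End-to-end orchestration of the automated landmarking workflow.

The full run mirrors the two-pass correspondence scheme: an arbitrary
subject is remeshed into a template and elastically registered to every
subject; the corresponded meshes are averaged into a mean shape; the mean is
re-registered to every subject and those second-pass correspondences are the
working ones.  Automated annotation of a subject is leave-one-out: the
remaining subjects' manual annotations are propagated onto the mean shape,
averaged (equal observer weighting) into landmark seeds, transported to the
held-out subject through the correspondences and finally refined at local
extrema.  Validation compares intra-observer, inter-observer and
inter-method errors with the full descriptive/ICC/Bland-Altman toolkit.

Femur and tibia are processed as independent correspondence problems that
share one per-subject reference frame, derived from the femoral posterior
condylar landmarks.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict

import numpy as np
import pandas as pd

from .agreement import (
    BlandAltman,
    ErrorSample,
    bland_altman,
    icc,
    landmark_errors,
    measurement_errors,
    outliers_per_subject,
    success_rates,
    summaries_to_frame,
)
from .frames import build_reference_frame, to_frame
from .landmarks import (
    AUTO_OBSERVER,
    AnnotationConfig,
    LandmarkSet,
    SeedTable,
    build_seed_table,
    annotate_subject,
    expert_mean_landmarks,
    load_landmark_catalog,
    propagate_landmark,
)
from .mesh import TriangleMesh
from .morphometry import MeasurementResult, load_measurement_catalog, measure_all
from .registration import CorrespondedMesh, RegistrationConfig, elastic_register, mean_shape
from .remesh import isotropic_remesh

__all__ = [
    "PipelineConfig",
    "CorrespondenceResult",
    "AgreementReport",
    "run_correspondence_stage",
    "run_leave_one_out",
    "run_validation",
    "run_phantom_rehearsal",
]

log = logging.getLogger("kneemorph.pipeline")

#: tolerance grids for success curves (mm), covering the reported ranges
LANDMARK_TOLERANCES = np.arange(0.5, 6.01, 0.5)
MEASUREMENT_TOLERANCES = np.arange(0.25, 3.01, 0.25)


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of a full run."""

    registration: RegistrationConfig = dataclasses.field(default_factory=RegistrationConfig)
    annotation: AnnotationConfig = dataclasses.field(default_factory=AnnotationConfig)
    template_edge_length: float = 1.0
    remesh_template: bool = True
    template_subject: str | None = None  # None -> first subject
    leave_one_out: bool = True
    seed: int = 0


@dataclasses.dataclass
class CorrespondenceResult:
    """Output of the two-pass correspondence stage for one bone."""

    template: TriangleMesh
    mean: TriangleMesh
    corresponded: dict[str, CorrespondedMesh]  # pass-2, keyed by subject
    pass1_residuals: dict[str, float]
    pass2_residuals: dict[str, float]


def run_correspondence_stage(
    subject_meshes: list[TriangleMesh], config: PipelineConfig | None = None
) -> CorrespondenceResult:
    """Template -> all subjects -> mean shape -> re-register mean to all.

    The template defaults to the (optionally remeshed) first subject.  The
    returned correspondences are the second-pass ones: with the cohort mean
    as the template, the elastic deformation each subject requires is
    smaller, so residuals typically drop relative to pass 1.
    """
    config = config or PipelineConfig()
    if len(subject_meshes) < 2:
        raise ValueError("need at least 2 subjects")
    names = [m.name for m in subject_meshes]
    if len(set(names)) != len(names):
        raise ValueError("subject mesh names must be unique")

    if config.template_subject is None:
        template_mesh = subject_meshes[0]
    else:
        template_mesh = next(m for m in subject_meshes if m.name == config.template_subject)
    if config.remesh_template:
        log.info("remeshing template %s at %.2f mm", template_mesh.name,
                 config.template_edge_length)
        template = isotropic_remesh(template_mesh, config.template_edge_length)
    else:
        template = template_mesh.copy()

    pass1: list[CorrespondedMesh] = []
    pass1_res: dict[str, float] = {}
    for m in subject_meshes:
        cm = elastic_register(template, m, config.registration)
        pass1.append(cm)
        pass1_res[m.name] = float(cm.residual.mean())
        log.info("pass1 %s: mean residual %.3f mm", m.name, pass1_res[m.name])

    mean = mean_shape(pass1)

    corresponded: dict[str, CorrespondedMesh] = {}
    pass2_res: dict[str, float] = {}
    for m in subject_meshes:
        cm = elastic_register(mean, m, config.registration)
        corresponded[m.name] = cm
        pass2_res[m.name] = float(cm.residual.mean())
        log.info("pass2 %s: mean residual %.3f mm", m.name, pass2_res[m.name])

    return CorrespondenceResult(
        template=template, mean=mean, corresponded=corresponded,
        pass1_residuals=pass1_res, pass2_residuals=pass2_res,
    )


# ---------------------------------------------------------------------------
# leave-one-out automated annotation
# ---------------------------------------------------------------------------

def _bone_subset(landmarks: LandmarkSet, bone: str, catalog) -> LandmarkSet:
    coords = {a: p for a, p in landmarks.coordinates.items()
              if a in catalog and catalog[a].bone == bone}
    return dataclasses.replace(landmarks, coordinates=coords)


def _seed_table_for_bone(
    manual: dict[str, list[LandmarkSet]],
    corresponded: dict[str, CorrespondedMesh],
    mean: TriangleMesh,
    bone: str,
    held_out: str,
    catalog,
) -> SeedTable:
    """Propagate every other subject's annotations to the mean; average; snap."""
    mean_cm = CorrespondedMesh.from_mesh(mean, source_target="mean")
    per_subject_means: list[np.ndarray] = []
    acronyms: list[str] | None = None
    for subject, sets in sorted(manual.items()):
        if subject == held_out:
            continue
        propagated = [
            propagate_landmark(_bone_subset(s, bone, catalog), corresponded[subject], mean_cm)
            for s in sets
        ]
        subject_mean = expert_mean_landmarks(propagated)
        if acronyms is None:
            acronyms = subject_mean.acronyms()
        per_subject_means.append(subject_mean.as_array(acronyms))
    if not per_subject_means:
        raise ValueError(f"no annotations left after holding out {held_out}")
    grand = np.mean(per_subject_means, axis=0)
    mean_landmarks = LandmarkSet("mean", "MEAN", dict(zip(acronyms, grand)), frame="RAW")
    return build_seed_table(mean, mean_landmarks)


def run_leave_one_out(
    manual: dict[str, list[LandmarkSet]],
    femur_corr: CorrespondenceResult,
    tibia_corr: CorrespondenceResult,
    held_out: str,
    config: PipelineConfig | None = None,
) -> LandmarkSet:
    """Automated annotation of ``held_out`` using only the other subjects.

    The femur is annotated first; its refined posterior condyle landmarks
    define the subject's reference frame, which the tibial refinement then
    uses (one frame per subject).  Subject keys of ``manual`` must match the
    corresponded-mesh names of both bones.
    """
    config = config or PipelineConfig()
    catalog = load_landmark_catalog()
    for corr in (femur_corr, tibia_corr):
        if held_out not in corr.corresponded:
            raise KeyError(f"held-out subject {held_out} has no correspondences")

    femur_catalog = {a: d for a, d in catalog.items() if d.bone == "femur"}
    tibia_catalog = {a: d for a, d in catalog.items() if d.bone == "tibia"}

    femur_seeds = _seed_table_for_bone(
        manual, femur_corr.corresponded, femur_corr.mean, "femur", held_out, catalog)
    tibia_seeds = _seed_table_for_bone(
        manual, tibia_corr.corresponded, tibia_corr.mean, "tibia", held_out, catalog)

    subject_cm = femur_corr.corresponded[held_out]
    # provisional frame from the propagated (unrefined) condylar seeds
    frame0 = build_reference_frame(
        subject_cm.vertices[femur_seeds["FMCP"]], subject_cm.vertices[femur_seeds["FLCP"]])
    femur_auto = annotate_subject(subject_cm, femur_seeds, femur_catalog, frame0,
                                  config.annotation)
    frame = build_reference_frame(femur_auto["FMCP"], femur_auto["FLCP"])
    tibia_auto = annotate_subject(tibia_corr.corresponded[held_out], tibia_seeds,
                                  tibia_catalog, frame, config.annotation)
    coords = {**femur_auto.coordinates, **tibia_auto.coordinates}
    return LandmarkSet(held_out, AUTO_OBSERVER, coords, frame="RAW")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AgreementReport:
    """Bundle of agreement statistics across comparison modes."""

    landmark_samples: dict[str, list[ErrorSample]]  # mode -> samples
    measurement_samples: dict[str, list[ErrorSample]]
    landmark_summary: pd.DataFrame
    measurement_summary: pd.DataFrame
    icc_table: pd.DataFrame
    bland_altman: dict[str, BlandAltman]  # measurement -> limits of agreement
    landmark_success: pd.DataFrame
    measurement_success: pd.DataFrame
    outlier_counts: dict[tuple[str, str], int]
    measurements: list[MeasurementResult]

    def mean_error(self, kind: str, mode: str) -> float:
        samples = (self.landmark_samples if kind == "landmark"
                   else self.measurement_samples).get(mode, [])
        if not samples:
            raise ValueError(f"no {kind} samples for mode {mode}")
        return float(np.mean([s.error for s in samples]))


def _subject_measurements(
    sets: list[LandmarkSet], frames: dict[str, object]
) -> list[MeasurementResult]:
    catalog = load_measurement_catalog()
    out: list[MeasurementResult] = []
    for s in sets:
        aligned = to_frame(s, frames[s.subject])
        out.extend(measure_all(aligned, catalog))
    return out


def run_validation(
    manual: list[LandmarkSet],
    auto: list[LandmarkSet],
    landmark_tolerances: np.ndarray = LANDMARK_TOLERANCES,
    measurement_tolerances: np.ndarray = MEASUREMENT_TOLERANCES,
) -> AgreementReport:
    """Intra-/inter-observer and inter-method agreement on a cohort.

    Reference frames are built per subject from the expert-mean condylar
    landmarks and shared by manual and automated measurements, replicating
    the manual-validation alignment rule.  INTRA statistics are skipped
    (with a log message) when no observer has repeated annotations.
    """
    by_subject: dict[str, list[LandmarkSet]] = defaultdict(list)
    for s in manual:
        by_subject[s.subject].append(s)
    auto_by_subject = {s.subject: s for s in auto}
    if set(auto_by_subject) - set(by_subject):
        raise ValueError("automated sets for subjects without manual annotations")

    # expert-mean frames, one per subject
    frames = {}
    for subject, sets in by_subject.items():
        em = expert_mean_landmarks(sets)
        frames[subject] = build_reference_frame(em["FMCP"], em["FLCP"])

    has_repeats = any(
        len([s for s in sets if s.observer == sets[0].observer]) > 1
        for sets in by_subject.values()
    )
    modes = ["INTRA", "INTER", "METHOD"] if has_repeats else ["INTER", "METHOD"]
    if not has_repeats:
        log.warning("no repeated annotations: skipping INTRA statistics")

    intra_sets = [
        s for sets in by_subject.values()
        for s in sets if s.observer == min(x.observer for x in sets)
    ]
    all_manual = list(manual)
    all_with_auto = all_manual + list(auto_by_subject.values())

    landmark_samples: dict[str, list[ErrorSample]] = {}
    measurement_samples: dict[str, list[ErrorSample]] = {}
    manual_meas = _subject_measurements(all_manual, frames)
    auto_meas = _subject_measurements(list(auto_by_subject.values()), frames)
    for mode in modes:
        if mode == "INTRA":
            landmark_samples[mode] = landmark_errors(intra_sets, mode)
            measurement_samples[mode] = measurement_errors(
                _subject_measurements(intra_sets, frames), mode)
        elif mode == "INTER":
            landmark_samples[mode] = landmark_errors(all_manual, mode)
            measurement_samples[mode] = measurement_errors(manual_meas, mode)
        else:
            landmark_samples[mode] = landmark_errors(all_with_auto, mode)
            measurement_samples[mode] = measurement_errors(manual_meas + auto_meas, mode)

    def _grouped(samples: list[ErrorSample]) -> dict[str, list[ErrorSample]]:
        g: dict[str, list[ErrorSample]] = defaultdict(list)
        for s in samples:
            g[s.item].append(s)
        return g

    landmark_summary = pd.concat(
        [summaries_to_frame(_grouped(landmark_samples[m])) for m in modes],
        ignore_index=True)
    measurement_summary = pd.concat(
        [summaries_to_frame(_grouped(measurement_samples[m])) for m in modes],
        ignore_index=True)

    icc_table = _icc_table(by_subject, auto_by_subject, manual_meas, auto_meas, has_repeats)
    ba = _bland_altman_per_measurement(manual_meas, auto_meas)

    landmark_success = _success_frame(landmark_samples, landmark_tolerances)
    measurement_success = _success_frame(measurement_samples, measurement_tolerances)

    all_samples = [s for m in modes for s in landmark_samples[m]]
    outliers = outliers_per_subject(all_samples)

    return AgreementReport(
        landmark_samples=landmark_samples,
        measurement_samples=measurement_samples,
        landmark_summary=landmark_summary,
        measurement_summary=measurement_summary,
        icc_table=icc_table,
        bland_altman=ba,
        landmark_success=landmark_success,
        measurement_success=measurement_success,
        outlier_counts=outliers,
        measurements=manual_meas + auto_meas,
    )


def _success_frame(samples: dict[str, list[ErrorSample]], tolerances: np.ndarray) -> pd.DataFrame:
    rows = []
    for mode, s in samples.items():
        curve = success_rates(s, tolerances, item=f"all/{mode}")
        for t, r in zip(curve.tolerances, curve.rates):
            rows.append({"comparison": mode, "tolerance_mm": float(t), "rate": float(r)})
    return pd.DataFrame(rows)


def _measurement_matrix(
    meas: list[MeasurementResult],
) -> dict[str, dict[str, dict[str, list[float]]]]:
    """abbreviation -> subject -> observer -> values (repeats in order)."""
    table: dict[str, dict[str, dict[str, list[float]]]] = defaultdict(
        lambda: defaultdict(lambda: defaultdict(list)))
    for r in meas:
        table[r.abbreviation][r.subject][r.observer].append(r.value)
    return table


def _icc_table(by_subject, auto_by_subject, manual_meas, auto_meas, has_repeats) -> pd.DataFrame:
    rows = []
    manual_tab = _measurement_matrix(manual_meas)
    auto_tab = _measurement_matrix(auto_meas)
    for abbrev in sorted(manual_tab):
        subjects = sorted(manual_tab[abbrev])
        entry = {"measurement": abbrev}
        if has_repeats:
            first_obs = {s: min(manual_tab[abbrev][s]) for s in subjects}
            reps = [manual_tab[abbrev][s][first_obs[s]] for s in subjects]
            k = min(len(r) for r in reps)
            if k >= 2:
                table = np.array([r[:k] for r in reps])
                entry["icc_intra"] = icc(table, "TWO_WAY_MIXED").value
        observers = sorted({o for s in subjects for o in manual_tab[abbrev][s]})
        inter = np.array([
            [float(np.mean(manual_tab[abbrev][s][o])) for o in observers]
            for s in subjects
        ])
        if inter.shape[1] >= 2:
            entry["icc_inter"] = icc(inter, "TWO_WAY_RANDOM").value
        if auto_tab[abbrev]:
            expert = inter.mean(axis=1)
            auto_vals = np.array([
                float(np.mean(auto_tab[abbrev][s][AUTO_OBSERVER])) for s in subjects
            ])
            entry["icc_method"] = icc(np.c_[expert, auto_vals], "TWO_WAY_RANDOM").value
        rows.append(entry)
    return pd.DataFrame(rows)


def _bland_altman_per_measurement(manual_meas, auto_meas) -> dict[str, BlandAltman]:
    manual_tab = _measurement_matrix(manual_meas)
    auto_tab = _measurement_matrix(auto_meas)
    out = {}
    for abbrev in sorted(manual_tab):
        if not auto_tab[abbrev]:
            continue
        subjects = sorted(set(manual_tab[abbrev]) & set(auto_tab[abbrev]))
        if len(subjects) < 2:
            continue
        expert = np.array([
            float(np.mean([np.mean(v) for v in manual_tab[abbrev][s].values()]))
            for s in subjects
        ])
        auto_vals = np.array([
            float(np.mean(auto_tab[abbrev][s][AUTO_OBSERVER])) for s in subjects
        ])
        out[abbrev] = bland_altman(expert, auto_vals)
    return out


# ---------------------------------------------------------------------------
# synthetic rehearsal (template + deformed cohort, full workflow)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RehearsalResult:
    """Everything a synthetic end-to-end run produces."""

    subjects: list
    manual: dict[str, list[LandmarkSet]]
    auto: dict[str, LandmarkSet]
    femur_corr: CorrespondenceResult
    tibia_corr: CorrespondenceResult
    report: AgreementReport
    truth_landmark_errors: dict[str, dict[str, float]]  # subject -> acronym -> mm
    truth_measurement_errors: dict[str, dict[str, float]]

    def mean_truth_landmark_error(self) -> float:
        return float(np.mean([e for sub in self.truth_landmark_errors.values()
                              for e in sub.values()]))

    def measurement_within(self, tol: float) -> float:
        errs = [e for sub in self.truth_measurement_errors.values() for e in sub.values()]
        return float(np.mean([e <= tol for e in errs]))


def run_phantom_rehearsal(
    n_subjects: int = 6,
    magnitude: float = 2.0,
    smoothness: float = 20.0,
    mesh_resolution: float = 2.0,
    sigma_intra: float = 1.0,
    sigma_inter: float = 1.5,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> RehearsalResult:
    """Generate a phantom cohort and run the complete workflow on it.

    A base knee phantom is deformed into ``n_subjects`` synthetic subjects
    (smooth fields, RMS ``magnitude`` mm, kernel ``smoothness`` mm); three
    simulated observers annotate each (observer 1 three times); the two-pass
    correspondence, leave-one-out automated annotation and full validation
    are then run exactly as they would be on clinical meshes.  Truth errors
    compare the automated landmarks and measurements against the phantoms'
    analytic ground truth.
    """
    from .phantoms import deform_knee, generate_knee, simulate_observers

    config = config or PipelineConfig(
        registration=RegistrationConfig(),
        template_edge_length=max(1.0, mesh_resolution),
    )
    base = generate_knee(subject="base", mesh_resolution=mesh_resolution, seed=seed)
    subjects = [
        deform_knee(base, magnitude, smoothness, seed=seed * 1000 + i + 1,
                    subject=f"s{i + 1:02d}")
        for i in range(n_subjects)
    ]

    manual: dict[str, list[LandmarkSet]] = {}
    for i, knee in enumerate(subjects):
        manual[knee.subject] = simulate_observers(
            knee.truth, knee.meshes, knee.subject,
            sigma_intra=sigma_intra, sigma_inter=sigma_inter,
            seed=seed * 1000 + 500 + i,
        )

    femur_corr = run_correspondence_stage([k.femur for k in subjects], config)
    tibia_corr = run_correspondence_stage([k.tibia for k in subjects], config)

    # corresponded meshes are keyed by mesh name; re-key by subject id
    femur_corr.corresponded = {k.subject: femur_corr.corresponded[k.femur.name]
                               for k in subjects}
    tibia_corr.corresponded = {k.subject: tibia_corr.corresponded[k.tibia.name]
                               for k in subjects}

    auto: dict[str, LandmarkSet] = {}
    for knee in subjects:
        auto[knee.subject] = run_leave_one_out(
            manual, femur_corr, tibia_corr, knee.subject, config)

    report = run_validation(
        [s for sets in manual.values() for s in sets], list(auto.values()))

    truth_lm_err: dict[str, dict[str, float]] = {}
    truth_ms_err: dict[str, dict[str, float]] = {}
    meas_catalog = load_measurement_catalog()
    for knee in subjects:
        a = auto[knee.subject]
        truth_lm_err[knee.subject] = {
            acr: float(np.linalg.norm(a[acr] - p))
            for acr, p in knee.truth.landmarks.items()
        }
        frame = build_reference_frame(a["FMCP"], a["FLCP"])
        auto_meas = {r.abbreviation: r.value
                     for r in measure_all(to_frame(a, frame), meas_catalog)}
        truth_ms_err[knee.subject] = {
            abbrev: abs(auto_meas[abbrev] - t)
            for abbrev, t in knee.truth.measurements.items()
        }

    return RehearsalResult(
        subjects=subjects, manual=manual, auto=auto,
        femur_corr=femur_corr, tibia_corr=tibia_corr, report=report,
        truth_landmark_errors=truth_lm_err, truth_measurement_errors=truth_ms_err,
    )
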