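# kneemorph

Automated anatomical landmarking and morphometric measurement of the distal
femur and proximal tibia from 3D bone + cartilage surface meshes.

Manual landmark annotation of knee surfaces — the basis of implant sizing,
meniscal allograft matching and morphometric risk-factor studies — takes an
expert tens of minutes per knee and varies between observers.  `kneemorph`
implements a fully automated alternative: a template mesh is elastically
registered onto every subject so that all surfaces share one vertex
topology, landmark seeds are propagated through those dense correspondences
in a leave-one-out design, and landmarks defined as extreme positions
("the most posterior point of the medial condyle") are refined to the
locally most extreme vertex in a reference frame anchored on the femoral
posterior condylar line.  The package also contains the complete validation
toolkit — intra-/inter-observer and inter-method error statistics,
ICC reliability, Bland–Altman limits, success-rate curves — and a synthetic
phantom generator with analytic ground truth so the entire pipeline is
testable without any clinical data.

## The method in brief

* **Correspondence.** Isotropic remeshing of one subject yields a template;
  rigid ICP plus a locally-affine nonrigid ICP (per-vertex affine field,
  graph-Laplacian stiffness relaxed over a decreasing schedule, matches
  gated by distance, normal compatibility and boundary exclusion) imposes
  the template topology on every subject.  Averaging the corresponded
  vertices gives a mean shape, which is re-registered to all subjects for
  the working correspondences.
* **Landmarks.** 23 named landmarks (15 extremum-defined, 8 constructed);
  seeds on the mean shape are built from the other subjects' manual
  annotations with equal observer weighting, transported by vertex index,
  then refined by a bounded geodesic extremum search
  (`argmax/argmin` of a frame coordinate within 10 mm, ties broken by a
  secondary axis then lowest index).
* **Measurements.** 15 axis projections `|coord_axis(a) − coord_axis(b)|`
  in the frame with x along the posterior condylar line (FMCP–FLCP), z the
  scanner table axis, y = z × x.
* **Statistics.** Euclidean / absolute-difference errors per comparison
  mode; type-7 quartiles with the 1.5·IQR outlier rule; ICC(A,1) from the
  two-way ANOVA mean squares; Bland–Altman bias ± 1.96·SD; success rates as
  the empirical CDF of errors.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Generate a synthetic six-knee cohort and run the complete workflow —
registration, mean shape, leave-one-out automated annotation, validation:

```bash
kneemorph phantom-rehearsal --n-subjects 6 --seed 1 --out runs/demo
```

which prints (numbers from this exact command):

```json
{
 "mean_truth_landmark_error_mm": 1.1191325459733286,
 "fraction_measurements_within_2mm": 0.9888888888888889,
 "mean_intra_mm": 0.9774769296302094,
 "mean_inter_mm": 1.7252694660350867,
 "mean_method_mm": 1.6902374289334134
}
```

Reading: automated landmarks land on average 1.12 mm from the phantoms'
analytic ground truth, and 98.9% of the morphometric measurements (15 per
subject) are within 2 mm of their closed-form truth values.  The three mean
landmark errors show repeat noise (INTRA, 0.98 mm) well below observer
disagreement (INTER, 1.73 mm), with the automated-vs-expert-mean error
(METHOD, 1.69 mm) at the same level as the inter-observer error — the
automated method is about as far from the expert consensus as the experts
are from each other, which is the design goal.  Per-landmark and
per-measurement tables, ICCs, success curves and Bland–Altman limits are
written as CSVs under `runs/demo/`.

Library use mirrors the CLI:

```python
from kneemorph import (read_mesh, run_correspondence_stage,
                       run_leave_one_out, run_validation)
```

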