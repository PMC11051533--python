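# Methods

`kneemorph` automates a task normally done by hand on clinical knee MRI:
placing named anatomical landmarks on 3D bone + cartilage surface meshes of
the distal femur and proximal tibia, and deriving linear morphometric
measurements from them.  This note documents the models, the parameters that
matter, the synthetic phantoms the package validates itself on, and the
design choices made where the design was genuinely open.

## The automated landmarking model

The core idea is template-based: if every subject's surface is re-expressed
with the topology of one common template, vertex *i* denotes (approximately)
the same anatomical location on every subject, and a landmark known on one
surface can be transported to all others by index.

1. **Template preparation.**  An arbitrary subject is isotropically remeshed
   (edge split / collapse / flip / tangential-relax cycle, with re-projection
   onto the original surface) to a uniform target edge length.  The default
   target is 1.0 mm for clinical meshes; the synthetic rehearsals use the
   phantom resolution (2.0 mm) since finer templates cannot add information
   that the phantom meshes do not contain.

2. **Correspondence by elastic registration.**  The template is rigidly
   aligned (point-to-surface ICP, closed-form update per iteration, stopping
   when the pose stops moving) and then deformed by a locally-affine
   nonrigid ICP: each template vertex carries a 3x4 affine transform, and

   `alpha * ||(M kron G) X||^2 + ||W (D X - U)||^2`

   is minimised by sparse least squares, where `M` differences transforms
   across template edges (first-order stiffness), `D` applies each transform
   to its own vertex and `U` holds the current closest points on the target.
   Correspondences are rejected (w=0) when farther than `max_corr_distance`
   (default 10 mm), when the template normal and the target triangle normal
   disagree by more than `normal_compat_threshold` (default 60 degrees) —
   the constraint that stops opposite surfaces of a thin structure from
   attaching to each other — or when the closest point lies on the open
   boundary of a field-of-view-cropped target.  The stiffness `alpha` is
   relaxed along a strictly decreasing schedule (default eight steps halving
   from 100 to ~0.8), with up to two correspondence/solve alternations per
   step, stopping early when the parameter change falls below 0.01 mm.
   Rationale for the locally-affine model: it is the standard formulation
   for "rigid then constrained elastic" template fitting, it is solvable
   exactly per step with a sparse factorisation, and its single stiffness
   knob maps directly onto the coarse-to-fine behaviour the workflow needs.

3. **Mean shape and second pass.**  The deformed templates share one
   topology, so the cohort mean shape is the vertex-wise average.  All
   subjects are then re-registered with the mean as the template; the
   second-pass correspondences are the working ones (the mean is closer to
   every subject than any individual is, so residual deformations are
   smaller).

4. **Landmark seeding (leave-one-out).**  Manual annotations of all
   subjects except the one being annotated are propagated onto the mean
   shape through the correspondences (barycentric coordinates in the
   nearest surface triangle, evaluated in the matching triangle of the mean).
   Observer repeats are averaged first, then observers, then subjects, so
   each observer carries equal weight regardless of repeat count.  The
   averaged landmark is snapped to its nearest mean-shape vertex (ties to
   the lowest index), yielding a seed table `acronym -> vertex index`.

5. **Automated annotation.**  Seed vertices are transported to the held-out
   subject by index.  Landmarks whose definition names an extreme position
   ("most posterior point of the medial condyle", ...) are then refined: the
   vertex maximising (or minimising) the relevant reference-frame coordinate
   is selected within a geodesic ball (edge-graph Dijkstra, default radius
   10 mm) around the propagated seed, with a secondary axis breaking exact
   primary ties and the lowest index breaking the rest; the winner is
   finally walked uphill along edges so the result is a genuine local
   extremum even when the ball argmax sits on the search boundary.  The
   bounded search is deliberate: an unbounded "most distal point" would jump
   to the wrong condyle.  Eight landmarks with constructed definitions
   (notch-depth fractions, view-verified cartilage points: FMCIP, FMCEP,
   FLCIP, FLCEP, FMCPP, FLCPP, TMCA, TLCA) are propagated without
   refinement, because no surface extremum defines them.  Candidate
   positions are restricted to mesh vertices throughout.

## Reference frame and measurements

All measurements are axis projections in a per-subject frame anchored on the
femoral posterior condylar line: z is the scanner table direction (taken as
the mesh file's +z, assuming correct patient positioning so only an axial
rotation remains), x is the FLCP-FMCP direction projected into the plane
perpendicular to z (+x lateral; a right-knee convention, with a flip flag
for unmirrored left knees), y = z cross x (+y anterior), origin at the
condylar midpoint.  The tibia uses the femoral frame of the same subject.
Each of the 15 catalogued measurements is `|coord_axis(a) - coord_axis(b)|`;
the notch AP size averages its medial (FMCP-Notch) and lateral (FLCP-Notch)
variants, which are near-equal by construction in the aligned frame.

When validating against manual annotations the frame is built from the
expert-mean FMCP/FLCP (so manual and automated measurements share one
alignment); a fully automatic mode builds it from the automated FMCP/FLCP
instead.  "ML notch" is computed like the rest but is carried as
not-clinically-validated in the catalog's provenance.

The epicondyle landmarks FME/FLE are refined along the mediolateral axis:
the epicondylar prominence protrudes mediolaterally (it anchors the femoral
width fML), and no anteroposterior surface extremum exists there — the
"anterior and distal" phrasing in the classical definition locates which
prominence is meant, not an extremisation direction.

## Agreement statistics

Three comparisons, each with its own ground-truth rule: INTRA (each repeat
of one observer vs the mean of the repeats), INTER (each observer's
repeat-averaged annotation vs the equal-weight expert mean), METHOD (the
automated result vs the expert mean).  Landmark errors are Euclidean
distances, measurement errors absolute differences.  Summaries: quartiles
by linear interpolation of order statistics (the common type-7 rule — the
convention is a free choice, fixed and documented for reproducibility), the
1.5*IQR outlier rule applied per item, mean +/- sample SD, success-rate
curves (empirical CDF of errors on 0.5-mm / 0.25-mm tolerance grids), and
per-subject outlier counts.

A caveat specific to synthetic cohorts: the ICC is a ratio of
between-subject variance to total variance, so its value depends on cohort
heterogeneity as much as on method agreement.  The phantom cohort's
between-subject spread (2 mm RMS deformations) is far smaller than the
anatomical spread of a clinical population, so phantom ICCs — especially
for the small mediolateral sizes, whose spread is comparable to observer
noise — are systematically lower than clinical ones and can go negative
without indicating any defect.  The error-based statistics (mm differences,
success rates) are the cohort-independent quantities to read.

Reliability uses the intraclass correlation for absolute agreement with a
single rater, computed from the two-way ANOVA mean squares:

`ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))`.

The two-way *mixed* (intra-observer) and *random* (inter-observer,
inter-method) models share this point estimate; the model label is carried
for interpretation.  A table with no variance at all is reported as ICC 1
with a degeneracy flag.  Bland-Altman bias and 1.96*SD limits of agreement
quantify inter-method differences per measurement.  Confidence intervals
and F-tests are out of scope (point estimates only).

## Synthetic phantoms

No clinical data ship with the package, so validation runs on stylised knee
phantoms: star-shaped surfaces r(u) = ellipsoid radius + Gaussian angular
lobes, cropped by a shaft-cut plane to emulate the scan field of view.
Femur-like: posterior and distal condylar lobes per side, trochlear lobes
with an anterior groove, epicondylar side lobes, and a deep intercondylar
notch indentation; tibia-like: two eminence spikes, posterior plateau lobes
with a posterior midline groove, and mediolateral plateau lobes.  Lobe
geometry is chosen so that every extremum-type landmark exists as a genuine,
well-separated local extremum of its frame coordinate — the property the
refinement step relies on; amplitudes and widths are in the anatomical
ballpark (condyles ~10 mm proud, notch ~16 mm deep, overall widths ~80 mm)
but the phantoms make no claim of anatomical accuracy: the acceptance
surface is landmark/measurement recovery, not realism.

Ground truth is defined on the continuous analytic surface, independent of
any mesh: extremum landmarks are found by bounded local optimisation
(Nelder-Mead in a tangent chart) seeded at the owning lobe's centre, with a
per-lobe angular bound (0.18-0.55 rad) that keeps the search inside the
lobe's territory — the analytic counterpart of the bounded geodesic search —
and chosen well below the separation to the nearest competing lobe.  When
building an undeformed phantom the optimum must be interior to the bound or
generation fails ("landmark not realised").  Constructed landmarks are
fixed surface directions; truth measurements are the projections of the
truth landmarks in the truth frame.

Inter-subject variation: a smooth random displacement field (sum of 12
Gaussian kernels, sigma = smoothness, normalised to a requested RMS over
the mesh vertices) is applied to mesh and analytic surface alike; truth
extrema are re-optimised on the deformed surface, so the truth tracks where
the extremum actually moved, not merely where the field carried the old
point.  Defaults for the rehearsal cohort: six subjects, RMS 2 mm,
smoothness 20 mm — enough shape variation to exercise the elastic
registration without self-intersection at the phantom scale.

Observer simulation: each observer draws a persistent tangent-plane bias
per landmark (SD 1.5 mm per component) and each repeat adds tangent jitter
(SD 1.0 mm); annotations are re-projected onto the mesh, as experts pick
surface points.  The sigmas emulate reported intra-/inter-observer
magnitudes of about 1 and 1.5 mm.  What the phantoms do *not* emulate:
segmentation error, cartilage/bone boundary ambiguity, image-resolution
effects on subtle ridges, observer disagreement about landmark *identity*
(as opposed to position), and left/right anatomy.  Passing the synthetic
rehearsal therefore demonstrates that the pipeline machinery recovers known
truth under controlled shape variation and observer noise — not that it
reaches any particular accuracy on clinical data.

## Numerical choices and edge cases

* Closest-point queries use a k-d tree over triangle centroids (k=12
  candidates) with exact point-triangle projection; correct when the true
  nearest triangle is among the k nearest centroids, which holds for the
  smooth, near-uniform meshes produced here.
* Duplicate vertices within 1e-6 mm are welded on load; STL always welds.
  Multi-component files keep their largest component.  Coordinates are
  treated as millimetres; no unit conversion is attempted.
* Geodesic distances are edge-graph shortest paths (Dijkstra), not exact
  polyhedral geodesics — sufficient for gating a local search.
* The sparse normal equations of the elastic step are solved with a direct
  factorisation; the stiffness block is built once per registration.
* Nearest-vertex snapping and extremum ties resolve to the lowest vertex
  index, making every stage deterministic; all synthetic generators are
  deterministic given their seed.
* Degenerate inputs raise early: empty meshes, faces with repeated indices,
  condylar landmarks that coincide or align with the table axis, ICC tables
  with fewer than two subjects or raters, already-aligned landmark sets
  being re-aligned.
* Remeshing refuses to continue when collapses would degrade the mesh below
  a minimal closed surface; deformation fields that flip triangle normals
  raise rather than return self-intersecting phantoms.

## Problem sizes

The rehearsal cohort uses ~1.9k-vertex femora and ~1.7k-vertex tibiae
(2 mm edges), six subjects, two registration passes per bone — 24 elastic
registrations in a full run, a few seconds each.  These sizes were chosen
as the smallest at which the phantom lobes are well resolved (edge length
comfortably below every lobe footprint) while keeping a complete rehearsal
in the minutes range; accuracy at these sizes is limited by the
vertex-candidate restriction (about half an edge length), which is also the
dominant term in the clinical method's resolution argument.

## Known limitations

* The registration is a standard locally-affine nonrigid ICP, not a
  reproduction of any specific published variant; it is validated by its
  contract (fixpoint, rigid equivariance, phantom landmark transfer), not
  equation-level identity with other implementations.
* Nearly flat regions give the correspondence field tangential slack; the
  resulting landmark drift mostly cancels in axis-projection measurements
  but dominates the landmark-position error budget.
* Notch-depth-fraction landmarks are propagate-only; their accuracy is
  purely that of the correspondences.
* Meshes are assumed single-connected-component surfaces in millimetres,
  one bone per file; multi-label surfaces and volumetric meshes are out of
  scope, as are angular morphometrics, statistical-shape-model analysis,
  and any acceleration beyond single-threaded execution.
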