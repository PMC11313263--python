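# Methods

This package analyses populations of 3D aortic surface models around
aortic valve surgery with two complementary unsupervised methods: a
statistical shape model (SSM) that summarises the population as a mean
shape plus principal modes of variation, and agglomerative hierarchical
clustering of per-subject shape vectors that finds morphological
subgroups.  Because no patient imaging is distributable, a synthetic
aorta generator supplies cohorts with known ground truth; every
downstream stage is exercised and tested against that ground truth.

## Synthetic aorta generator

Each aorta is a tube of circular cross-sections swept along a
"question-mark" centreline — a vertical ascending segment, a
semicircular arch, and a descending segment with sinusoidal
out-of-plane tortuosity — using parallel-transport frames (torsion-free
and well-defined on straight segments, unlike Frenet frames).  The
radius profile linearly interpolates four control radii (root,
mid-ascending, distal-ascending, descending) and adds a Gaussian sinus
bulge just above the annulus.  The tube is left open at the annulus and
diaphragm, matching how clinical models are cut; closure for volume
measurement is an explicit capping step.

Axial rings are allocated to the three anatomical segments in fixed
proportions (30% / 25% / 45%) and sampled uniformly within each
segment, so ring *i* is the same anatomical station in every subject.
This makes cross-subject correspondence anatomical by construction and
makes the innominate cut (trimming to the ascending aorta) an exact,
shared ring-index operation.

### Cohort model

Group sizes, ascending-aorta surface-area distributions, and covariate
distributions (age, height, weight) default to the study cohort this
generator emulates: pre-operatively 15 AVR / 15 Ozaki / 13 Ross / 4
valve-sparing subjects with ascending areas of 10 989 ± 2 711,
13 421 ± 2 726, 9 031 ± 2 125 and 14 658 ± 3 125 mm² respectively
(post-operative arm analogous).  Per subject a latent standard-normal
size draw fixes the target ascending area; height and age are drawn
with configurable correlation to it (default 0.4 each, matching the
reported size-age/size-height associations); BSA uses the Mosteller
formula (Du Bois available) and BMI its definition.  Each mesh is
rescaled so its realised ascending surface area equals the drawn target
exactly, then perturbed with 0.5 mm isotropic vertex noise emulating
segmentation error — so realised group means/SDs match the configured
targets up to normal sampling error.

### Shape-size coupling and group signatures

Correlation distance — the default clustering metric — is invariant to
uniform scaling of a subject's registered coordinates, so *pure* size
differences are invisible to the clustering stage.  We verified this
directly: clustering the drawn surface areas themselves (a perfect size
axis) isolates ≥ 70% of the Ross group in one of four clusters in only
about a third of replicates, given how much the group area
distributions overlap.  The clean Ross clustering the clinical study
observed therefore implies the Ross aortas were *shaped* differently,
which the study describes explicitly (elongated ascending aorta and
wide arch pre-operatively; elongated ascending with enlarged sinus
post-operatively).  The generator encodes this as three mechanisms:

1. **Group shape signatures** — dimensionless multipliers on the base
   anatomy per group.  Ross: ascending elongation 1.30 and relative
   arch width 1.25 pre-operatively; elongation 1.30 and sinus factor
   1.4 post-operatively.  Other groups use neutral signatures.
2. **Valve morphotype** — each subject is bicuspid (BAV) or tricuspid
   (TAV) with the group-specific frequencies of the emulated cohort
   (which was 28 BAV / 13 TAV pre-operatively).  BAV aortopathy is
   modelled as a discrete mid/distal-ascending dilatation of e^0.12.
   This gives the non-Ross pool genuine discrete cluster structure,
   as valve morphotype does in real aortic cohorts.
3. **Rectified allometry** — proportional (relative) dilatation and
   tapering are treated as pathological features of the large-size
   tail: they scale with max(u, 0) (u = cohort-standardised size) at
   0.10 and 0.04 per SD, with only a small linear baseline (0.02/SD)
   across the whole range.  Normal-range aortas thus share similar
   proportions while dilated ones diverge — and the small-aorta Ross
   group stays morphologically compact, as its tight clustering in the
   study implies.  Descending tortuosity and relative arch width also
   grow with size (0.45 and 0.10 per SD), reproducing the reported
   large-size phenotype (dilated, curved descending aorta).

Independent log-normal jitter (σ = 0.02 on proportions) models
residual anatomical idiosyncrasy.  These constants were chosen to
reproduce the study's qualitative contrasts — most of the Ross group in
one cluster, size-linked mode 1 — and are fixed defaults of the
generator, not fitting parameters.

### What the generator does not emulate

Real segmentations have local surface detail (lumpy walls, branch
stubs, remeshing artefacts) that a four-radius parametric tube cannot
represent; consequently the synthetic mode-1 variance share (~0.85) is
far higher than the ~0.24 of the clinical SSM, whose variance is spread
over many local modes.  Cohort-dependent quantities (template diameters
in mm, inertia percentages, regression p-values) are therefore *not*
reproduced numerically; tests cover them through analytic and
property-based checks instead.  Passing tests show the pipeline's
machinery is correct and that the study's qualitative findings follow
from its stated cohort structure — not that the generator is a model of
any individual anatomy.

## Shape model

Registration is translation-only (each subject's barycentre to the
origin): rotation and scale remain part of the modelled variability, so
mode 1 acts as a size mode.  The atlas is a point-distribution model:
the template is the pointwise mean, and PCA (divisor n − 1) of the
flattened subject-minus-template displacement fields gives orthonormal
modes, eigenvalues (mm²), per-subject scores and cumulative inertia.
Mode 1's sign is fixed so its scores correlate positively with subject
surface area; other modes orient their largest loading positive.  A
kernel-based diffeomorphic atlas would estimate correspondence as part
of fitting; with generator-exact correspondence, PCA on displacements
preserves the same analysis surface (template, modes, inertia, scores)
and is testable against a brute-force covariance eigendecomposition.
An optional resolution kernel (Gaussian smoothing of displacement
fields over the template, width λ_W in mm) suppresses features finer
than the kernel before PCA; the stiffness parameter λ_V of deformation
models has no PDM analogue and is recorded with a logged warning.

Template diameters are *equivalent circular* diameters,
2·sqrt(A/π) of the plane section perpendicular to the centreline —
robust to non-circular sections; when a plane cuts the curved vessel
more than once, the section loop nearest the landmark is measured.

## Clustering

Shape vectors are the registered, flattened XYZ coordinates (one row
per subject).  Dissimilarities support euclidean, manhattan,
correlation (1 − Pearson r), cosine and Mahalanobis metrics;
zero-variance vectors are rejected under the correlation metric rather
than silently assigned distance 0.  The agglomeration engine applies
the Lance–Williams recurrence directly to the supplied dissimilarities
for all seven linkages (single, complete, average, centroid, median,
Ward, McQuitty/WPGMA with α_i = α_j = ½, β = γ = 0).  Centroid, median
and Ward updates are only geometrically interpretable for
squared-Euclidean input; they are computed verbatim with a logged
caveat, because the method of record pairs a non-Euclidean metric
(correlation) with WPGMA and the engine must be metric-agnostic.
Ties break deterministically on the smallest (id_a, id_b) pair.
Dendrograms cut either at a height (connected components of merges
below it) or to a cluster count (undo the last k − 1 merges); labels
are contiguous 1..k in first-leaf order.  The default configuration is
correlation + McQuitty with a height cut of 1.0, overridable per run.

## Morphometrics

Centrelines of ring-structured grids are per-ring centroids with
chord-length arc parameterisation (general mesh skeletonisation is out
of scope).  Tortuosity is arc length over endpoint chord — the standard
clinical definition, ≥ 1, equal to 1 only for straight vessels.  SA/V
is measured on the capped surface with cap area included (volume
requires closure, and the convention is stated so external comparisons
are well-defined).  The ascending/descending diameter ratio uses
equivalent diameters at the mid-ascending and mid-descending stations
taken from each subject's generating parameters (config-driven for
external data).

## Statistics

Test statistics are computed from their defining formulas; tail
probabilities use the standard chi-squared (regularised incomplete
gamma), normal and t distributions.  Pearson's chi-squared uses no
continuity correction — verified to reproduce the study's printed
statistics (30.88, 22.64, 5.80, 13.55) on its published contingency
tables exactly to two decimals.  Kruskal–Wallis uses mid-ranks and the
standard tie correction; Dunn's pairwise z uses joint ranks with the
tie-corrected variance, two-sided normal p-values, and optional
Bonferroni / Holm / Benjamini–Hochberg adjustment (default none, as the
study does not state one).  OLS adds an intercept automatically and
reports per-coefficient two-sided t-tests and r²; "bivariate"
anthropometric models are two-predictor fits always containing age.

## Numerical choices and problem sizes

* STL stores float32; round-trips tolerate quantisation, and vertex
  welding is by exact coordinate match after quantisation (no
  tolerance parameter).
* Mesh volume refuses open surfaces (boundary-edge count reported)
  rather than capping silently.
* Default grids are 80 axial × 24 circumferential points (5 760
  coordinates per subject) — discretisation errors on analytic test
  geometries are well under the 0.5–2% test tolerances; analytic
  checks use finer grids where the tolerance demands it.
* The pre-/post-operative cohorts are independent populations; nothing
  in the pipeline treats them as paired.
* Oracle-equivalence tests run 50 random problems with n ≤ 8 over all
  35 linkage × metric combinations; the null-calibration check uses
  2 000 simulated datasets (4 groups × 12); the Ross-recovery
  experiment uses 20 replicates of the full 47-subject cohort.

## Known limitations

* External STL meshes can be read, measured and clustered only if they
  share the generator's ring-grid layout; arbitrary meshes have no
  correspondence estimation and are excluded from the SSM.
* The dendrogram height of the default cut is data-scale dependent;
  synthetic correlation distances are numerically much smaller than
  the clinical ones (parametric shapes decorrelate less), so
  cluster-count cuts are the robust choice on synthetic cohorts.
* Centroid/median linkage can produce non-monotone dendrograms;
  height cuts are well-defined only for monotone linkages.
* The mapping from a cohort's smallest-model surface area to kernel
  widths used by deformation-based SSM tools is not computable from
  published information; kernel widths are configuration inputs here.
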