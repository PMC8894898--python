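# Methods

This note documents the models and procedures implemented in `hippoasym`,
the defaults they ship with, and the choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Inputs and canonicalization

Label volumes are read from NIfTI-1 and reoriented to RAS+ (axis 0
left→right, axis 1 posterior→anterior, axis 2 inferior→superior) before
anything else happens. Left and right hippocampi are identified purely by
label ID under a registered *dialect* (default: FreeSurfer `aseg`, 17 =
left, 53 = right); image-side heuristics are never used, so
radiological-vs-neurological display conventions cannot flip a result.
Voxel indices are 0-based and physical coordinates are voxel-center ×
spacing. How a particular segmentation tool's native output is converted
to an integer label map is left to the user.

## Surface extraction and the 14 shape features

Meshes are extracted by marching cubes at iso-level 0.5 on the binary
mask zero-padded by one voxel (guaranteeing closed surfaces at array
borders), with vertices in mm. A binary mask carries no sub-voxel
information about surface *orientation*, so the raw isosurface is a
beveled staircase whose area exceeds that of smooth anatomy by roughly 9%
— and, being an orientation artifact, this excess does not shrink as the
object grows. The mesher therefore applies three Taubin
(shrinkage-compensated λ|μ Laplacian, λ = 0.5, μ = −0.53) relaxation
passes by default. The iteration count was fixed once from analytic-ball
calibration runs at radii 5–20 voxels: three passes recover sphere area
and volume to ~1% at r ≥ 10 while topology (vertex/face structure) is
untouched. `smooth=False` retains the exact voxel-geometry surface (a
single voxel yields the octahedron with V = 1/6 mm³, A = √3 mm²), which
is also what the topology-sensitive tests use. Consequences to keep in
mind: features of structures only a few voxels across are systematically
shrunk (a ball of radius 5 loses ~10% volume), and mesh-derived features
of rotated masks agree only to ~0.01% because marching-cubes cell
splitting is not rotation-symmetric.

The 14 descriptors and their conventions:

* `mesh_volume` — divergence-theorem volume of the closed mesh;
  `voxel_volume` — foreground count × voxel volume. The two are reported
  separately; `surface_to_volume_ratio` = `surface_area` / `mesh_volume`
  so that numerator and denominator come from the same surface.
* `sphericity` = (36π V²)^⅓ / A with V the mesh volume.
* `max_3d_diameter` — largest pairwise vertex distance, computed on the
  convex hull when the mesh exceeds 2000 vertices (identical value,
  lower cost).
* The three `max_2d_diameter_*` features bin vertices to grid planes by
  rounding the orthogonal physical coordinate to the voxel pitch and take
  the largest in-plane distance within any one bin; "slice" is the axial
  plane (orthogonal axis = inferior–superior), "column" coronal, "row"
  sagittal.
* Axis lengths are 4√λᵢ with λ₁ ≥ λ₂ ≥ λ₃ the eigenvalues of the
  *population* covariance (divide by N) of foreground voxel-center
  coordinates; `elongation` = √(λ₂/λ₁), `flatness` = √(λ₃/λ₁). Ties are
  broken by a stable descending sort.

These definitions are frozen; other radiomics implementations differ in
small details (2D-diameter binning in particular), so cross-tool feature
values should be compared with care.

## Asymmetry biomarker

AI(lh, rh) = (lh − rh)/(lh + rh), computed on *uncorrected* measures —
the contralateral side is the internal reference, which removes head-size
and age effects by construction. Normative limits are the mean ± 2·SD and
± 3·SD of the AI over **all** healthy-control scans (repeat scans
included; sample SD, n−1). The limits are centered on the healthy-control
mean rather than on zero because control cohorts show a small negative
volume AI (slightly larger right hippocampus); centering on zero would
bias side-specific flags. Scans outside the limits are assigned a side by
the metric's direction of change under sclerosis: volume falls on the
affected side (AI below the lower limit ⇒ left-abnormal), the
surface-to-volume ratio rises (AI above the upper limit ⇒ left-abnormal).

Accuracy metrics are computed on the unilateral-HS vs
all-other-epilepsies contrast only; bilateral-HS scans are excluded both
from sensitivity/specificity/F1 and from the ROC analysis (which, with
the default cohort, contrasts 37 unilateral-HS against 86 other-epilepsy
scans). F1 is defined as 0 when there are no predicted positives. The
AUC is the Mann–Whitney statistic normalized by n₊·n₋ with ties counted
½, computed on |AI|; it is invariant under monotone transforms of the
scores.

## Normative volume model and effect sizes

vol ~ z(eTIV) + z(age), ordinary least squares on healthy controls only,
with z-scores computed from the same healthy-control rows and stored in
the model so it can be applied to every scan. Sex is deliberately not a
covariate. The corrected volume subtracts the covariate effect but keeps
the intercept, staying in mm³; since a location shift cancels in Cohen's
*d*, effect sizes are identical either way. Separate models are fitted
per hemisphere (and would be per segmentation method). Effect sizes are
pooled-SD Cohen's *d* with the patient group first, so volume loss in
left HS yields a negative *d* against controls.

## Feature ranking

The ranking classifier answers one question — which shape feature carries
the most discriminative signal — and is not itself the diagnostic. Inputs
are the **absolute** AI of each of the 14 features, one row per patient
scan (healthy controls excluded). The absolute value matters: sclerosis
may affect either hemisphere, so the signed AI shifts of left- and
right-sided cases point in opposite directions and would cancel in a
linear decision function; the magnitude is the side-agnostic signal. A
linear SVM with the conventional default regularization (C = 1) is fitted
over 20 repeats of 5-fold cross-validation. Folds are drawn by shuffling
*patients* (not scans) with a repeat-specific seed and splitting them into
five balanced groups, so all scans of one subject stay on one side of
every boundary; fold draws leaving a training fold single-class are
rejected and redrawn. Features are standardized with training-fold
statistics only. Each fit contributes |w| normalized to sum 1; the final
importance is the mean over all 100 fits (ranks 1–14 by descending
importance). Same seed ⇒ bit-identical ranking. Class imbalance is left
unweighted. Note that perfectly correlated features split their weight,
so a duplicated signal appears as two features with half importance each.

## Test–retest robustness

A *session* is the unit of repetition: for patients, all scans of one
subject on the same calendar day; for healthy controls, a greedy
chronological chain — the earliest unassigned scan anchors a session that
absorbs every scan within 365 days of it. Only sessions with ≥ 2 scans
count. MAPE is the session-averaged mean absolute deviation from the
within-session mean, relative to that mean, in percent; it is
scale-invariant. ICC(2,1) — two-way random effects, absolute agreement,
single measurement — is computed from the first two scans of every
session (earliest dates, ties broken by scan ID):
ICC = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE)). Methods are
compared by two-sided paired *t*-tests on the per-session percentage
deviations (the session is the natural pairing unit since it is the outer
summand of the MAPE); identical error vectors return p = 1 by convention.

## Synthetic data: what it emulates and what it does not

**Measurement level.** The default cohort reproduces the emulated study's
structure: 406 healthy-control scans from 354 subjects and 126 patient
scans from 105 subjects (18/19/3 left/right/bilateral HS, 86 other
epilepsies), with 41 re-scan sessions (20 patient same-day sessions —
one of three scans — plus 21 control within-a-year repeats; 31 further
control follow-ups at > 365 days form no session). Scans are constructed
as lh = M(1 + AI), rh = M(1 − AI), so the *observed* per-scan AI is
exactly Normal(group mean, `ai_sd`): the healthy-control mean AI defaults
to −0.007 and HS groups are shifted by standardized effects (volume AI:
−4.165 SD left, +4.203 SD right). Re-scan noise is split into a dominant
shared (bilateral) component and a small antisymmetric component
(defaults: volume CV 0.035, AI re-scan SD 0.005), because per-side
repeatability error in segmentation pipelines is strongly correlated
between hemispheres — were it independent, a per-side CV of realistic
size would alone exceed the entire AI spread. The bilateral mean M
follows a linear model in z-scored eTIV and age (slopes 200 and −150 mm³
per control SD) with 300 mm³ residual SD around a 3500 mm³ mean, and HS
groups lose 250 mm³ (unilateral) or 400 mm³ (bilateral) of bilateral
mean. S/V ratios are generated the same way (mean 0.65 mm⁻¹, AI SD 0.02,
effects +3.0/−3.0 SD for left/right HS; bilateral HS raises both sides by
15%). The S/V effect sizes are a design choice, not a published value:
the study prints only the AUC of the absolute S/V AI, and under Gaussian
AIs no single effect size reproduces both large volume-style effects and
a mid-0.8s AUC — real patient AIs are heavy-tailed in a way a Gaussian
generator is not. Passing tests on these cohorts therefore validate the
estimators under clean Gaussian conditions; they do not certify
performance numbers on clinical data. Twelve of the 14 shape features
carry no group signal (noise AIs around fixed nominal levels); volume-
derived features and S/V carry the planted effects.

**Voxel level.** Phantoms are bent ellipsoids (default semi-axes 7×18×6.5
mm, quadratic inferior bend) voxelized at 1 mm. `atrophy` scales the
implicit radius by atrophy^⅓ so it acts as a *volume* factor; fraying
multiplies the radius by 1 + a·f(u), where f is a band-limited noise
field on the direction sphere (ten seeded cosine plane waves,
≈ zero-mean/unit-SD, angular frequency 4 by default); optional spheres
carve cavities into the lateral body. A labelled subject places the left
phantom in the low-x half of the grid and a mirrored right phantom in the
high-x half under the default dialect, with a ground-truth record. The
phantoms emulate the *geometry* that drives the biomarker — volume loss
and surface irregularity — not MR intensities, segmentation-method
disagreement, or hippocampal subfield anatomy.

All generators are pure functions of (config, seed).

## Numerical choices and degenerate inputs

Empty masks, single-class inputs, zero pooled SD, zero AI spread,
constant covariates, zero session means, and open meshes raise explicit
errors rather than returning sentinel values. Sample SDs use n−1
throughout except the axis-metric covariance (population convention,
documented above). Problem sizes in the test suite — 200-seed recovery
runs, 500-replicate AUC calibration, 50-seed phantom screens at ~30×60×30
voxel grids — were chosen as the smallest sizes at which Monte-Carlo
error is comfortably below the tolerances being checked.

## Known limitations

* Features of structures a few voxels across are biased by mesh
  relaxation (see above); at hippocampal scale the effect is ~1%.
* The greedy one-year control-session rule is one of several defensible
  readings of "all scans within one year"; chains longer than a year are
  split at the first scan outside the anchor's window.
* No harmonization across scanners/protocols, no nonlinear age effects,
  no bilateral-HS detector, no per-subject aggregation of repeated scans
  in the classification metrics.
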