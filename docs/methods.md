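# Methods

`atlasvol` re-implements, as tested library code, a three-stage atlas-based
morphometry pipeline for small-animal structural MR, the water-maze
search-strategy analysis that accompanies it, and the group-statistics layer
that connects regional brain volumes to behavioral readouts in a
dose-response design (sham plus four prenatal X-ray doses: 0.10, 0.33, 0.66
and 1.00 Gy).  Because the underlying animal data are not publicly
deposited, the package ships a synthetic-data module that generates every
input with known ground truth; all pipeline-level claims are therefore
claims about recovery of known truth, and all table-level claims are
recomputations from the published group summaries (mean ± SEM with group
sizes 18/15/7/11/10, 61 animals in total).

## Image model and conventions

Volumes are NIfTI-1, resolved to RAS axis order on load.  Voxel indices are
0-based; world coordinates are millimetres with voxel centres at
`origin + index*spacing`, so a structure's volume is exactly
`voxel count x prod(spacing)`.  The study acquisition was 80 um isotropic;
the synthetic phantoms use 64^3 grids at 0.16 mm so the full pipeline runs
in minutes on one CPU, and every spacing-dependent default (control-point
spacing, dilation radii) is expressed in voxels so it transfers across
resolutions.

## Stage 1 — pre-processing

*Bias correction.*  The intra-scan inhomogeneity is modelled as a
multiplicative smooth field, estimated by least squares in the
log-intensity domain as a 3D polynomial of total degree 2 within the brain
mask and gauge-fixed to mean 1 there.  The cited retrospective methods do
not pin down a parametric family; a low-order polynomial is deterministic,
testable, and adequate for the smooth synthetic fields.  Correction is
idempotent to <0.5% by construction (refitting a corrected image yields a
near-flat field).

*Brain masking.*  The nonzero support of the atlas label map is resampled
into the subject grid (nearest neighbour) and dilated with a discrete
Euclidean ball of radius 3 voxels — the study's stated dilation — so that
imperfect affine pre-alignment does not clip cortex.

*Intensity normalization.*  Per image, an affine intensity map sends the
masked 1st/99th percentiles onto those of the first subject of the cohort.
The reference subject is a documented assumption (the alternative — a
common template — is not stated in the source protocol); percentile
anchoring makes the map robust to tails, and the operation is exactly
invariant to any per-image affine intensity change.

## Stage 2 — registration and template construction

Transforms map fixed-domain world points into the moving domain
(pull-back), so warping is one interpolation.  Three families:

- **Rigid** (3 translations + 3 rotations, fixed-axis x-y-z convention,
  rotation about the fixed-image centre).
- **Affine** (adds 3 log-scales and 3 shears; 12 parameters).
- **FFD**: cubic B-spline displacements on a control lattice, default
  spacing 5 voxels — the study's final 400 um control spacing at 80 um
  resolution.  The lattice covers the domain with a 3-point margin; the
  control coefficients are exactly the spline coefficients, so evaluation
  uses order-3 spline interpolation without prefiltering.

Linear stages maximize normalized mutual information (32-bin joint
histogram, subsampled to at most 12k voxels per pyramid level) by a Powell
search over a 3-level coarse-to-fine pyramid, preceded at the coarsest
level by an exhaustive integer-shift search.  Out-of-domain samples are
border-extended rather than dropped: excluding them rewards transforms
that shrink the overlap onto informative voxels (the well-known NMI
overlap pathology), which in early testing produced spurious 15% scale
errors.  The FFD stage minimizes mean SSD plus a bending-energy penalty
(squared second differences of control displacements, weight 1e-3) by
L-BFGS with analytic gradients, on a coarse-to-fine lattice schedule (2x
final spacing, then final).  SSD is valid at this stage because
intensities were normalized cohort-wide in stage 1; the metric, bins,
iteration caps and penalty weight are all config-exposed since the
upstream tools' internals are not published.  Trilinear sampling of the
moving image inside the SSD cost carries a small but systematic boundary
bias (propagated structure volumes off by 5–7% on phantoms); a
cubic-spline sampling phase therefore follows the trilinear phase in the
final non-rigid round and in the atlas-labeling registration, cutting
phantom volume-recovery error roughly in half.  Because each cubic line
search costs about three trilinear ones, its iterations and function
evaluations are both capped.  The data term is evaluated only on the
mask's bounding box and masked voxels — a pure speed optimization, since
the term carries no information outside the mask.  Both optimizers are
deterministic; the config records a seed only for provenance.

Template construction follows the published order exactly: (i1) rigid
alignment of every image to an external reference (the synthetic atlas, in
place of the public in-vivo atlas) and voxelwise averaging; (i2) affine
registration of every image to that average, re-averaging; (i3…) repeated
FFD registration to the previous average with **geometric centring** —
the control-point mean displacement over subjects is subtracted from every
FFD, making the cohort mean displacement exactly zero — followed by
re-averaging.  The non-rigid repeat count R defaults to the study's 10;
phantom-scale analyses use R=3, which the iteration log shows is already
past the point where the average stops changing materially at this
geometry scale.  Whether the original pipeline re-estimated or refined the
FFD each round is unstated; the default refines the previous round's
estimate (a `restart_ffd` flag restores re-estimation).  "Average" means
the voxelwise arithmetic mean of the warped intensity-normalized images.

Labels are assigned to the final template by affine+FFD registration of
the atlas to the template and nearest-neighbour propagation.  Approximate
FFD inverses, needed to carry template labels onto subject grids, use a
damped fixed-point iteration (step 0.5, cap 40, residual tolerance about
0.01 voxel); the damping keeps the iteration contractive where the
displacement Jacobian would make the plain iteration diverge.  For
propagation over whole subject grids the composed mapped-coordinate
field (smooth by construction) is evaluated on every second voxel and
interpolated trilinearly before the nearest-neighbour label lookup,
which speeds propagation several-fold at negligible coordinate error.

The control-point spacing deserves a note on units.  The study used a
0.4 mm final control spacing (5 voxels at its 80 um resolution).  The
phantom grids are 0.16 mm, where 5 voxels would mean 0.8 mm — half the
deformation resolution relative to brain anatomy — and measurably worse
volume recovery.  The pipeline therefore fixes the control spacing in
physical terms: its default is 3 voxels (0.48 mm) at phantom resolution,
while the registration-level default remains 5 voxels so that runs at the
study's native resolution reproduce the study's setting.

## Stage 3 — volumetry

Template labels travel to each subject through the inverse of its
template-construction chain, the 39 atlas labels merge into 19 structures
of interest via a packaged tab-separated table, and volumes are counted.
Only the ventricle grouping (cerebral aqueduct, lateral, third, fourth) is
fixed by the source description; the remaining 39→19 grouping
(left/right pairs plus one midline label) is the package's documented
assumption.  Whole-brain volume is the union of the 19 structures, so
normalized volumes sum to 100% by construction.  Group summaries report
mean ± SEM with N per dose group and a top-dose percent-change column;
absolute volumes use the decrease convention (100·(control−top)/control),
normalized volumes that increase (ventricles) use the increase convention,
and each row carries an explicit direction flag.  Normalized means are
mean-of-ratios (per-subject normalization, then averaging); the
ratio-of-means is emitted alongside because the published normalized
tables agree with both at printed precision.

## Water-maze strategy analysis

Trials are 2D timestamped tracks in a 150 cm pool with a 15 cm hidden
platform.  The original strategy calls were manual; the package replaces
them with a deterministic rule cascade over path features computed on a
10 Hz resampled track: path efficiency (ideal/actual length), corridor
occupancy toward the platform, wall-band occupancy (outer 15% of the
radius), a platform-distance annulus occupancy, dwell fractions in focal
zones (circles of twice the platform diameter at the target and at the
densest off-target focus), scanned pool-area fraction (grid cells within
12 cm of the path), heading monotonicity and turn rate, and net
revolutions about the pool centre.  The cascade assigns exactly one of
nine substrategies (three per class: spatial, non-spatial systematic,
repetitive looping); every threshold is a config field with the defaults
listed in `ClassifierConfig`.  Because the original numeric criteria are
unpublished, correctness is defined against the synthetic trajectory
generator: nine stochastic path models, one per substrategy, each
constructed to express its defining feature (a direct corridor walk, a
detoured approach, focal search at the correct/incorrect focus, central
lawnmower scanning, a persistent random walk, annulus chaining at the
platform distance, wall-hugging loops, tight drifting circles).  On the
seeded 90-trial batch the cascade recovers ~99% of substrategy labels and
100% of class labels; chance level for nine substrategies is 100/9 =
11.11%, against which per-subject usage percentages are tested with
one-sample t-tests.

## Statistics

One-way ANOVA accepts raw per-subject values or printed summaries; the
summary route reconstructs SD_i = SEM_i·sqrt(N_i), within-group sums of
squares Σ(N_i−1)SD_i², and between-group sums from the weighted means, so
the published F values are recomputable from the tables alone (total brain
107.9, cerebellum 143.0 at df (4, 56) — matching the printed 108 and 143).
Post-hoc comparisons are control-vs-dose t-tests on the pooled
within-group variance with Bonferroni multiplication.  Pearson
correlations across the behavior x volume family are adjusted by
Benjamini–Hochberg step-up; pairs with a constant vector are flagged
undefined and excluded from the family.  Two-way and repeated-measures
designs used for time-course readouts are deliberately out of scope: they
are routine package-level statistics that contribute no recomputable
printed number here.

## Synthetic data: what it does and does not emulate

The phantom atlas is a brain-shaped ellipsoid (semi-axes 26/22/20 voxels)
containing a central ventricle ellipsoid (closed-form volume, used for
analytic checks) and 18 tissue structures formed by a capacity-constrained
power diagram: seed points are placed loosely anatomically (bilateral
pairs mirrored across the mid-sagittal plane), and additive weights are
calibrated, then an exact deferred-acceptance assignment enforces integer
voxel quotas matching the sham-group normalized fractions of the published
tables.  Sub-labels (39) reproduce the merge bookkeeping.  Structure
intensities are distinct T2-like levels with partial-volume smoothing; the
levels alternate between spatially adjacent structures so that every
internal boundary carries an intensity step well above the noise scale —
without that property an intensity-driven registration has no signal at
those boundaries, which is a deliberate idealization relative to real T2
contrast (where, e.g., brainstem subdivisions are nearly isointense and
the real pipeline leans on atlas priors instead).

Dose-effect cohorts regenerate the parametric geometry per subject: a
volumetric scale drawn around the group factor (the ratios of published
whole-brain group means: 1.000/0.984/0.939/0.858/0.772), per-structure
relative multipliers (ratios of published normalized means), an optional
dorsal third-ventricle protrusion at 1.00 Gy (budgeted inside the
published ventricular enlargement, since the printed +44% already
includes the dorsal swelling), then a random smooth B-spline warp
(amplitude 1 voxel), a smooth multiplicative bias field (±10%) and
additive Gaussian noise (SD 4 on ~45–240 intensity levels).  A smooth
FFD systematically under-recovers the focal protrusion (isolated
experiments: ventricle volume −12% with the protrusion vs −1% without),
which keeps top-dose ventricular volumetry the hardest part of the
recovery problem — as it is for real deformation-based morphometry of
focal abnormalities.
The per-subject volume jitter (lognormal, CV 3.5%) matches the within-
group dispersion implied by the published control SEM.  Ground truth is
counted from the warped label map before intensity simulation.  Default
group sizes are the study's 18/15/7/11/10; the pipeline-scale condition
(`demo_dose_effects`) keeps the same effect sizes but reduces to three
groups (0.00/0.66/1.00 Gy) sized 6/5/5 so that template construction with
R=3 completes in roughly ten minutes on one CPU.

What passing tests show: that the pipeline recovers known geometry-driven
volume effects through the full registration/template/propagation chain at
phantom contrast and noise levels, and that the statistics reproduce the
published summary-level numbers exactly.  What they do not show: behaviour
on real RARE-sequence image characteristics (Rician noise, susceptibility
artifacts, anatomical detail far richer than blobby power-diagram cells),
or agreement of the strategy cascade with the original manual calls —
Table-5-style real-data correlations are explicitly not reproducible and
are replaced by synthetic r-recovery tests.

## Numerical choices and degenerate inputs

Zero-variance groups yield a flagged infinite F (or F=0 when means also
tie) rather than an exception; one-sample t on constant data is flagged
the same way.  Open/closed arm-entry ratios with zero closed entries are
flagged undefined rather than infinite.  Label resampling refuses linear
interpolation; empty propagated foregrounds and empty masks raise
immediately as registration-failure signals.  Percentile normalization
rejects degenerate ranges (p1 = p99).  Registration convergence is flagged
per subject but never silently aborts a template build; warnings are
collected in the model.

## Known limitations

The FFD similarity is SSD-only (NMI is available for the linear stages);
bending-weight and iteration defaults were chosen for phantom scale and
should be re-examined for real 80-um data.  The deferred-acceptance
partition can leave a few-voxel satellite per structure (<1.5% of a
structure's volume).  The strategy generator and classifier are
co-designed; accuracy against them bounds, but does not measure,
agreement with human raters.
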