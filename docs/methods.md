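# Methods

This note documents the models, numerical choices and limitations of the
pvgradient pipeline, in the order data flows through it.

## Phantom model

The synthetic subject is a miniature brain on an isotropic grid (default
64³ voxels at 1 mm):

* **Ventricles** — two axis-aligned ellipsoids (halfwidths default
  4 × 10 × 6 mm, centers ±8 mm off the midline). The bilateral lateral
  ventricle volume (LVV) of the default geometry is ≈ 2 ml.
* **Choroid plexus** — a curved strip of voxels on the posterior inner wall
  of each ventricle, grown inward until the target volume is met (exact to
  half a voxel per hemisphere). A `chp_norm` target may be given instead of
  an absolute volume; it is converted using the subject's own ICV.
* **White matter** — the shell of Chebyshev (L∞) distance 1…14 mm around
  the ventricles; **cortical GM** the next 3 mm; everything else is
  background. ICV is the volume of all labelled voxels (≈ 140 ml for the
  default geometry). Absolute volumes are therefore ~10× smaller than adult
  brains, but all statistics run on ICV-normalized values, which are in the
  physiological range (chp_norm ≈ 10⁻³, LVV/ICV ≈ 1.5%).
* **Lesions** — spheres (default radius 3 mm) placed uniformly at random
  fully inside WM, mutually non-overlapping, with bounded retries (an error
  names the constraint if placement is infeasible).

**Injected ratio field.** In WM, the noise-free T1w/FLAIR ratio is

    ratio(d) = ratio_baseline + gradient_slope · min(d, gradient_range_mm)

with d the Chebyshev distance (mm) from the ventricle margin.
`ratio_baseline` is the value at the margin (d = 0). Chebyshev distance is
chosen deliberately: it is the metric induced by the 3×3×3 dilation kernel
used by the band module, so band k sits exactly at distance k and the
noise-free expected band mean is exact, not approximate. FLAIR WM intensity
is fixed at an arbitrary reference (100); T1w is set voxelwise to realize
the target ratio; GM, CSF and lesion compartments get distinct plausible
intensities (FLAIR 110/25/160, ratios 0.7/1.2/0.55). `noise_sd` is additive
Gaussian noise on both modalities *before* the ratio, expressed as a
fraction of the WM FLAIR reference, and per-subject global affine
distortions (log-normal gain, Gaussian offset) are applied to each modality
so the histogram calibration has real work to do.

## Cohort generative model

`CohortSpec` samples per-subject covariates and outcomes; defaults are the
study conditions every simulation in the test suite uses:

| parameter | default | meaning |
|---|---|---|
| n_per_group | 75 / 141 / 64 | CS / RRMS / PPMS subjects |
| age (mean ± SD, years) | 45±13 / 42±11 / 51±10 | per group, clipped 18–85 |
| female proportion | 0.60 / 0.70 / 0.45 | per group |
| centers | 2 equal | acquisition-center factor |
| disease duration (years) | Γ(2.0)·4.5 / Γ(2.2)·5.0 | RRMS / PPMS; absent in CS |
| chp_base, chp_sd | 9·10⁻⁴, 2·10⁻⁴ | normalized ChP level and noise |
| chp_group_shift | 0 / 1.5·10⁻⁴ / 0.5·10⁻⁴ | additive ChP group effect |
| chp_duration_slope | 8·10⁻⁶ /year | RRMS only |
| LVV (log-normal, ml) | median 1.8 / 2.4 / 2.8, σ=0.35 | phantom scale |
| lvv_log_coupling | 1.5·10⁻⁴ per log-ml | logarithmic ChP–LVV term (group-centred) |
| chp_lesion_coupling | 4000 lesions per unit chp_norm | drives lesion counts (Poisson) |
| ratio_baseline, gradient_slope, range | 1.05, −0.01/mm, 6 mm | control-group profile |
| group_gradient_depth | 0 / −0.04 / −0.07 | extra margin depression per group |
| chp_ratio_coupling | −45 per unit chp_norm | ChP–gradient coupling (below) |
| subject_intercept_sd | 0.02 | global per-subject profile shift |
| band_noise_sd | 0.01 | per-band noise (table-level sampling only) |

**Plateau-preserving coupling.** Group depth and the ChP coupling act on
the ratio at the ventricle margin and decay linearly to zero at the
gradient range R: a subject's margin depression δ shifts the baseline by δ
and the slope by −δ/R, so the far-field plateau is unchanged. The implied
true regression slope of band-k mean on chp_norm is
`chp_ratio_coupling · (1 − min(k, R)/R)` — strongest in the innermost
bands and zero beyond the range, which is the decaying band-wise
association pattern the analysis is designed to detect. The log-LVV term is
centred on each group's median so configured group shifts remain the exact
expected group contrasts recorded in the truth table.

`sample_cohort_table` draws the covariate/outcome table directly (fast path
for statistical simulation); `generate_cohort` realizes the same draw as
image volumes: ventricle halfwidths scaled to the sampled LVV (truncated at
the largest ventricle that still fits the grid with its WM and cortex
shells), ChP voxels targeting the sampled chp_norm, the subject's
baseline/slope injected into the ratio field. Both are bit-reproducible
under a fixed seed.

## Calibration

Monotone piecewise-linear quantile matching on 101 evenly spaced levels,
with end-segment clamping outside the within-mask intensity range; the
template is the mean of the reference subjects' quantile functions
(reference set configurable: all subjects, or controls only). Duplicate
quantile knots are collapsed; a constant image inside the mask is an error.
This is the simplest monotone nonlinear histogram calibration; no spatial
registration is involved (templates are histogram-level).

Two properties matter and are verified by the tests:

* a per-subject affine intensity distortion is undone *exactly* (piecewise-
  linear maps compose exactly with affine maps at the knots), and smooth
  nonlinear monotone distortions are undone to well below 1% in band means;
* calibration forces every subject's within-mask distribution onto the
  template, so the **absolute** level of the calibrated ratio is anchored
  to the template, not to any subject's raw intensities. Global
  between-subject ratio offsets are removed by construction (that is the
  point of the step), and with noisy images the anchored level carries a
  small multiplicative offset (quantile matching of noise-broadened
  distributions plus the ≈(1+cv²) expectation bias of a ratio of noisy
  images; ≈ +0.5% at 5% noise). Band *contrasts* — the gradient relative to
  the plateau, group differences, band-wise association slopes — are
  unaffected; analyses of this pipeline interpret those contrasts, never
  the absolute ratio level.

The denominator floor for the ratio defaults to 10⁻⁶ × the median positive
FLAIR intensity; voxels at or below it are flagged invalid (NaN), never
silently zero.

## Bands

Default connectivity 26 (3×3×3 box kernel, matching the common
morphological-dilation default in FSL-style pipelines; 6-connectivity
available). Band k equals the Chebyshev distance-k shell of the ventricle
mask intersected with non-lesional WM — verified voxel-for-voxel against a
distance-transform oracle on random phantoms. The dilation source is the
full ventricle lumen (ventricle label ∪ ChP). Band b1 is constructed and
stored but flagged out of analysis by default (partial-volume rationale);
empty bands are kept as empty with a warning and reported as missing, not
zero.

## Statistics

* **ANCOVA / post-hoc.** OLS `outcome ~ group + covariates`; adjusted group
  means are model predictions at the numeric-covariate means with equal
  weights over factor levels (a conventional marginal-means reference
  grid). Pairwise contrasts use the studentized-range ("tukey") adjustment
  by default — exact for pairwise contrasts under balance, the Tukey–Kramer
  approximation otherwise; an "mvt" option integrates the multivariate t
  over the actual (singular) contrast correlation by seeded Monte Carlo.
  The two agree closely; adjusted p-values are clipped to never fall below
  the unadjusted p. Rank-deficient designs raise an error naming the
  aliased term.
* **Regressions.** Listwise deletion per model with n reported; two-sided
  tests, α = 0.05; 95% CIs; adjusted R². The ChP–LVV comparison fits
  `chp_norm ~ log(LVV) + covariates` against the linear analogue and
  reports both adjusted R²; non-positive LVV rows are excluded and counted.
  Covariate sets are configurable per analysis; the defaults are age+sex
  for the volume/duration associations and age+sex+center for the group
  comparison and the band-wise regressions.
* **Band-wise association.** Nine regressions (b2…b10) of band mean on
  chp_norm; Benjamini–Hochberg correction across the bands actually fitted,
  within one patient group (the family is per group, not across groups);
  all-missing bands shrink the family and the effective m is reported.
  `bh_adjust` delegates to the standard step-up implementation and is
  tested against the textbook formula.
* **Duration stratification.** Cut-off 10 years; a duration exactly at the
  cut-off goes to the *long* group (the boundary is otherwise undefined);
  missing durations are excluded and counted.
* **Mixed model.** `ratio ~ group × band + age + sex + center` with a
  random intercept per subject, REML. If the default optimizer fails on
  boundary cases (near-zero random-effect variance) a derivative-free
  restart is attempted; non-convergence is flagged in the result with
  diagnostics, never silently replaced.

## Pipeline

A run is fully described by a serializable `RunConfig` (YAML); the config
copy, templates, per-subject tables, statistics JSON and a log are written
to the output directory, and the same config + seed reproduces the tables
and JSON byte-identically. A subject failing any stage is excluded from
statistics with a logged reason; the run aborts only if fewer than two
usable subjects remain.

## Problem sizes used in the test suite

Simulation-based checks use sizes chosen to give stable Monte Carlo
estimates at desk scale: 20 random 64³ phantoms for the band-geometry
equivalence; 8 noise-free subjects for calibration invariance; 40 noisy
subjects for gradient recovery; 500 simulated cohorts (n = 60) each for the
null calibration and the power scenario of the band-wise association; 1000
null cohorts (n = 30/group) for the family-wise error of the adjusted
pairwise tests; 200 replicates each for the log-vs-linear model selection
and the mixed-model recovery. The band-wise power scenario sets the
coupling so that the *weakest* of the inner bands (b4) has a true slope of
3× the analytic slope standard error, making b2/b3 proportionally larger.

## What the phantom does and does not show

The generator emulates the statistical structure the analysis assumes —
gradients flattening with distance, group-level ChP enlargement,
ChP–lesion and ChP–band-ratio couplings, a logarithmic ChP–LVV
relationship, center/age/sex covariate structure — with exactly known
truth. It makes no attempt at anatomical realism: no gyri, no skull or
extra-cerebral CSF compartment, no spatially varying bias fields (only
global affine distortions), no scanner-specific contrast, and absolute
volumes scaled down ~10×. Passing tests therefore demonstrate the
correctness and calibration of the *pipeline* (geometry, calibration
algebra, estimator behaviour, error rates), not the performance of any
segmentation method or the anatomical validity of band placement in real
brains; in real-data mode the label volumes are taken as given.

## Known limitations

* The calibration family (piecewise-linear quantile matching, 101 knots) is
  one reasonable monotone nonlinear choice; spline variants would differ in
  the tails.
* Bands use Chebyshev distance; "k mm from the ventricles" is exact along
  the axes and diagonal-inflated elsewhere. Euclidean or geodesic bands are
  out of scope.
* ICV is the labelled-voxel count; a different ICV estimator shifts
  normalized values multiplicatively but not group contrasts.
* The absolute calibrated ratio level is template-anchored (see above);
  between-study comparisons of raw levels are not meaningful.
* EDSS is carried as a covariate but not modelled ordinally; the analysis
  is cross-sectional throughout.
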