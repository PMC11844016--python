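# Methods

`petsurv` implements the quantitative-PET biomarker workflow for
time-to-event outcomes: lesion delineation and SUV/MTV/TLG computation on
3D PET volumes, Cox proportional-hazards modelling with optimal-cutpoint
binarization, a paired bootstrap test on the difference of two hazard
ratios, and the two-cohort explorative/validation protocol.  Because no
public patient-level dataset accompanies this workflow, the package ships
first-class synthetic-data generators whose ground truth makes every stage
testable; this note records the models, the defaults, and the design
choices behind both.

## Quantitative PET parameters

For a delineated region of interest on an SUV-scaled volume:

* `SUV_max` — maximum voxel SUV; `SUV_mean` — arithmetic mean;
* `MTV` — metabolic tumor volume, voxel count × voxel volume, in ml;
* `TLG = MTV × SUV_mean` — total lesion glycolysis (dimensionally SUV·ml;
  tables report it in "ml" following the field's convention).

Per patient, the `_prim` parameters are computed on the primary tumor and
the `_all` parameters on the union of primary plus all nodal lesions:
`SUV_all` is the overall maximum, `MTV_all` the cumulative volume, and the
overall `SUV_mean` is **volume-weighted**,
`SUV_mean_all = Σ SUV_mean_i · MTV_i / MTV_all`, so that
`TLG_all = SUV_mean_all × MTV_all = Σ TLG_i` exactly.  The volume-weighted
reading is forced by additivity: it is the only definition under which the
"overall mean times cumulative volume" rule reproduces the sum of
per-lesion TLG (asserted to 1e-9 relative tolerance in the tests).  A
plain average of per-lesion means would not.

## Background-adaptive delineation

The delineator grows, per seed, a 26-connected region above the threshold

    T = BG + β · (lesion_max − BG),      β = 0.39 by default,

where `lesion_max` is the maximum SUV in the current region and `BG` the
local background, estimated as the mean SUV over a shell around the region
(1-voxel gap, 2 voxels thick by default; voxels of other lesions are
excluded from both shells and regions).  Iteration stops when the relative
volume change drops below `convergence_tol` (1e-3) or after
`max_iterations` (50), the latter raising an error carrying the last two
volumes.  On the first iteration the single seed voxel has no meaningful
shell; the global median SUV serves as the initial background estimate
(lesions occupy a small fraction of the field of view, so the median sits
on the background).  A seed not strictly above that estimate, or below the
first threshold, raises "no lesion at seed".  Seeds falling inside an
already-delineated region attach to it; colliding grown regions merge,
with the first seed's role deciding primary vs node.

The β = 0.39 background-corrected fixed-fraction scheme is the standard
choice for FDG lesions; β is exposed in `DelineationConfig` and recovered
MTV is non-increasing in β.  Manual contour correction is out of scope by
design: corrected masks are data, and enter through the same
`LesionSet`/NIfTI interface as automatic ones.

## Synthetic phantoms

`generate_phantom` renders ellipsoidal lesions of uniform uptake on a
uniform background, adds Gaussian noise on the SUV scale, then applies an
isotropic Gaussian PSF specified by its FWHM.  Noise before blur keeps the
noise correlated at the PSF scale, as in reconstructed PET images, while
remaining a deliberately simple image model: no sinogram/reconstruction
simulation, no attenuation, no motion.  Ground-truth masks are the
pre-blur ellipsoid voxelizations (voxel centers inside the ellipsoid), so
the partial-volume bias of the delineator is a measurable quantity rather
than a confound.  Tests pin: the voxelized sphere volume against a
voxel-counting oracle and its convergence to 4/3·π·r³ as the grid is
refined; exact recovery of noiseless uniform lesions for any 0 < β < 1;
and recovery of a 6-mm-FWHM-blurred 10-mm sphere within 15% of 4.19 ml.

## Synthetic cohorts

`generate_cohort` draws per-patient event times from an exponential
(constant-baseline) proportional-hazards model,

    rate_i = λ0 · exp( β_TLG · g(TLG_all,i) ),

with `g` selectable as identity (per ml), log, or a threshold step — the
binarized-biomarker model.  Censoring combines an administrative horizon
with uniform dropout.  The exponential baseline is a deliberate choice:
Cox estimation does not use the baseline shape, so the simplest closed
form suffices for parameter-recovery tests.

Defaults define the study conditions and are not tuned per test: 431
patients (split 366/65 by `split_cohort` at fraction 366/431), lognormal
TLG_all with median 150 ml and σ_log = 1.1 (placing ~27% of patients above
290 ml), a step at 290 ml with β_TLG = log 4, baseline hazard 0.002 events
per month, 60-month horizon, 25% uniform dropout — yielding on the order
of 75–90 FFDM events per cohort, a realistic event yield for this disease
setting.  Covariates (sex, age 61 ± 9, T/N/UICC stage, chemotherapy, HPV
status with ~51% unknown) are drawn from category frequencies typical of a
stage-IV-dominated oropharyngeal chemoradiation population and are
independent of TLG by default, so multivariate adjustment tests have a
known answer; `confounding_strength` couples T-stage to TLG when
confounded scenarios are wanted.  Per-patient PET parameters are built
bottom-up: total TLG is split over one primary (Beta(6, 1.5) share) and
0–5 nodes (Dirichlet), each lesion gets `SUV_mean ~ U(3, 9)` and
`MTV = TLG / SUV_mean`, so every aggregation identity holds by
construction.  The OS endpoint reuses 0.75× the FFDM linear predictor
with a higher baseline (0.003/month); it exists to exercise the endpoint
switch, not to model any particular OS structure.

All randomness in one generator call derives from a single
`numpy.random.default_rng(rng_seed)` stream; identical configs give
bit-identical outputs.

What the generator does **not** emulate: scanner heterogeneity,
uptake-time effects, non-proportional hazards, informative censoring,
correlated covariates (unless switched on), or measurement error linking
the imaging and cohort halves.  Passing tests therefore demonstrate the
statistical machinery is correct under the stated model, not that the
biomarker conclusions transfer to any particular clinical population.

## Cox regression and Kaplan–Meier

The Cox partial likelihood is maximized by Newton iteration with
step-halving from β = 0, convergence at 1e-9 on the coefficient max-norm,
at most 50 iterations.  Ties are handled by Efron's method by default
(more accurate when ties come from coarse time recording), Breslow
optionally; without ties the two agree to 1e-10.  Standard errors come
from the inverse observed information; confidence intervals are
`exp(coef ± 1.96·SE)` and p-values are two-sided Wald.  Degeneracies raise
typed errors rather than returning numbers: no events, constant
covariates, singular information (including covariates constant within
every event risk set), and monotone likelihoods — detected when a
coefficient passes |β| > 15, reported with the direction of divergence.

A specialized exact path (`binary_cox`) handles the single-binary-covariate
case: for a 0/1 covariate every Efron/Breslow risk-set quantity reduces to
at-risk and event counts per tie block, which do not depend on β, leaving
a scalar Newton iteration over precomputed arrays.  It reproduces the
general engine to 1e-9 (asserted) and makes the cutoff sweep and the
bootstrap roughly an order of magnitude faster.

`km_curve` is the product-limit estimator with the standard convention
that patients censored at an event time count as at risk at that time.
`collinearity_screen` reports pairwise squared Pearson correlations
(complete cases per pair; zero-variance parameters yield flagged NaNs).

Endpoint semantics: FFDM is operationalized as event = first distant
metastasis with death-without-metastasis treated as censoring; a composite
death-or-metastasis reading is equally defensible and is obtained by
encoding the event flags accordingly in the cohort table — the engine is
agnostic to which reading produced them.

## Optimal cutoff and its caveat

`optimize_cutoff` fits a univariate Cox model on `parameter > v` for every
observed value `v` and returns the admissible candidate with the smallest
Wald p (ties broken toward larger HR, then smaller cutoff).  Admissibility
requires ≥ 10% of patients and ≥ 3 events on each side — an unconstrained
search degenerates at extreme values where a near-empty group can produce
an arbitrarily extreme fit.  The search is invariant under strictly
monotone transforms of the parameter (same partitions, same p sequence).

The returned p-value is a **maximally selected statistic** and is
anti-conservative under the null: `examples/05_cutpoint_inflation.py`
measures a roughly 5–8× inflation of the nominal 5% level at n = 150.
This is documented, not "corrected": the pipeline's answer to it is
frozen-cutoff validation on independent data, and analytic corrections for
maximally selected statistics are out of scope.

## Bootstrap comparison of hazard ratios

`bootstrap_hr_compare` tests whether biomarker 1 carries a different
hazard ratio than biomarker 2 on the same patients.  Per resample the SAME
patient indices are drawn for both biomarkers (paired design — required
for the difference HR1 − HR2 to be meaningful); both binarized Cox models
are refitted and the difference recorded.  The resampling contract is
`default_rng(seed).integers(0, n, size=(n_samples, n))`, one documented
stream for the whole run.  Resamples where either fit is degenerate (an
empty or event-free group, a monotone likelihood, or non-convergence) are
excluded and counted; more than 20% degenerate resamples aborts with
advice.  The default number of samples is 10^5.

The two-sided p-value is `min(1, 2·min(P(D ≤ 0), P(D ≥ 0)))` over retained
differences, floored at `1/(kept+1)` so 0 is never reported.  Taking the
minimum of both tail fractions (rather than `2·min(q, 1−q)` with a single
`q`) makes the self-comparison — all differences exactly zero — yield
p = 1, and makes the p-value exactly invariant under swapping the two
biomarkers.  One-sided alternatives are available.  The cutoffs are held
fixed across resamples; a variant that re-optimizes the cutoff inside each
resample would answer a different (procedure-level) question and is
deliberately not implemented.

## Study pipeline

`run_explorative` chains: (1) univariate metric Cox for clinical
covariates (entered as the customary binarizations: age > 61, T > 2,
N > 1, UICC > III, male sex, no chemotherapy, HPV negative) and the six
PET parameters; (2) PET parameters below the trend threshold (p < 0.1 —
chosen so borderline parameters are not discarded before binarization)
advance to cutoff optimization, the rest are dropped; (3) paired bootstrap
prim-vs-all per advancing parameter family; (4) multivariate Cox of each
advancing PET parameter separately with the clinical covariates
significant in step 1 — separately because the MTV/TLG family is strongly
collinear (pairwise R² > 0.8 under the default generator, mirroring the
screen the package provides); (5) Kaplan–Meier curves per binarized group.
Binarization direction is always "parameter > cutoff = high risk".

`run_validation` applies externally supplied cutoffs verbatim: no search
code runs, the report's provenance carries the frozen values, and a cutoff
that leaves a group empty or event-free becomes a flagged degenerate row
rather than an exception.  `subgroup_analysis` repeats the explorative
logic per stratum (patients with unknown stratum values excluded, strata
with < 2 events skipped with a log entry, multivariate skipped when no
clinical covariate is significant in the stratum); subgroup reports are
marked not independently validated.  Missing PET parameters (NaN) are
handled by complete-case analysis per fit, which is how cohorts with
volume-only (no SUV) patients enter MTV analyses.

`cohort_summary` reports counts with percentages of the total cohort size
(one decimal) per categorical covariate — missing values form their own
"n/a" category so percentages per covariate total 100 within rounding —
plus mean ± SD and median age.

## Numerical and testing choices

* Test oracles are independent by construction: an explicitly coded
  partial likelihood maximized by `scipy.optimize` for small-n Cox fits
  (exhaustive over all 5-patient event/group patterns, plus random n ≤ 8);
  lifelines (with a statsmodels PHReg fallback where lifelines' Newton
  fails on small extreme groups) for the cutoff sweep and the duplicate
  bootstrap loop; R's `survival::coxph` was used as an additional
  arbitration during development.
* Replicate-based checks use fixed seed ranges and scaled sizes chosen
  once: HR-recovery calibration at 50 replicates of n = 500 (mean HR
  within 5% of truth, CI coverage within [90%, 99%]); change-point
  recovery at 25 replicates of n = 800; bootstrap stabilization compared
  at 20k vs 40k prefix-shared samples; the end-to-end study runs at the
  full 366/65 scale with 10^4 bootstrap samples.
* Floats round-trip exactly through the cohort CSV (`%.17g` writing,
  round-trip parsing); NIfTI round-trips preserve spacing and therefore
  MTV; all writers are deterministic for identical inputs.

## Known limitations

* The delineator is a single-threshold region grower: lesions whose
  uptake is not well above their local background (the cases needing
  manual correction in practice) will be under-segmented; no claim is
  made about necrotic cores or multi-focal uptake within one lesion.
* The exponential event-time model cannot express non-proportional
  hazards, so proportionality diagnostics beyond visual log-log KM
  inspection are out of scope.
* The optimized-cutoff p-value is reported as defined, anti-conservative
  under the null; only the validation stage provides calibrated evidence.
* Bootstrap comparisons require both binarizations to be admissible on
  the full data; very small cohorts or extreme cutoffs abort early by
  design.
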