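# Methods

This note documents the statistical model behind `mwfatlas`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real data.

## Growth models and their parameters

Regional myelin water fraction (MWF) trajectories are modeled as sigmoid
functions of gestation-corrected age `x` (days, referenced to 40 weeks
gestation, measured from birth; no internal rescaling — all rates are
reported per day). Eight forms are registered:

| model | k | form |
|---|---|---|
| gompertz | 3 | α·exp(−exp(β − γx)) |
| modified_gompertz | 4 | α·exp(−exp(β − γx) + δx) |
| bleasdale_nelder | 4 | (α + βx^δ)^(−1/γ) |
| richards | 4 | α·(1 + β·exp(γ(δ − x)))^(−1/δ) |
| stannard | 4 | α·(1 + exp(−(β + γx)/δ))^(−δ) |
| tanh | 4 | α + β·tanh(γx − δ) |
| logistic | 3 | α·(1 + exp(β − γx))^(−1) |
| general_logistic | 6 | α + (β − γ)·(1 + ζ·exp(−β(x − δ)))^(−1/ε) |

Two caveats are deliberate. The Richards form reuses δ as both location and
shape, and the general logistic reuses β as both plateau term and rate;
these are the forms as conventionally tabulated in this literature and are
implemented verbatim rather than silently replaced by textbook variants.
Relatedly, the 4-parameter tanh form has an offset independent of its
amplitude and therefore strictly *nests* the 3-parameter logistic (the
identity α·(1+e^{β−γx})^{−1} = (α/2)(1+tanh((γx−β)/2)) maps the logistic
onto the β=α subfamily); the two families tie in RSS only up to the extra
degree of freedom, which BIC then penalizes.

For the modified Gompertz the parameters read directly as biology: α is the
MWF scale at the transition from rapid to slow growth, β the developmental
lag, γ the rapid growth rate, δ the late growth rate that keeps the curve
off a hard asymptote. `derived_metrics` exposes exactly this relabeling.

Analytic parameter gradients are implemented for gompertz,
modified_gompertz, logistic and tanh — the atlas model's gradient (needed
for uncertainty propagation) is analytic. The four power-law-entangled
forms use central finite differences with steps scaled to parameter
magnitude; a property test pins every gradient against an independent
finite-difference oracle at 1e-5 relative (per-parameter scale).

## Fitting

Levenberg–Marquardt nonlinear least squares (`scipy.optimize.least_squares,
method='lm'`), unweighted, cross-sectional (each subject contributes one
point per region; no within-subject correlation structure is modeled).
Tolerances: relative RSS change < 1e-10 (`ftol`), 2000 function
evaluations per start. No box constraints are imposed during optimization.

Sigmoid fitting is basin-sensitive, so each fit uses a moment-style
heuristic start plus a seeded 10-point Latin-hypercube multi-start
(log-uniform scale factors in [1/2, 2]); the least-RSS solution is kept and
is never worse than the initialization. Initialization per family:

* Gompertz family: α₀ = 1.05·max(y); γ₀ from the slope of ln(−ln(y/α₀))
  regressed on age over the central tertile of the age range; β₀ = γ₀ ×
  (age at half-plateau); δ₀ = slope of y vs age over the final age
  quartile divided by α₀, floored at 0.
* Logistic: the analogous logit linearization; tanh, Richards, Stannard,
  Bleasdale–Nelder and the general logistic are seeded from the logistic
  solution through their approximate reparameterizations.

Model comparison uses BIC = n·ln(RSS/n) + k·ln(n) with k the
free-parameter count. The Gaussian σ term would add the same constant to
every model on shared data and cannot change a ranking, so it is omitted.
A perfect fit (RSS = 0) yields BIC = −∞ and is flagged. Ties break toward
fewer parameters, then lexicographic name. Failed fits stay in the ranking
with BIC = +∞.

## Wild bootstrap

`wild_bootstrap` regenerates responses as y*ᵢ = ŷᵢ + ε̂ᵢ·vᵢ and refits from
the original solution. The weight law is Rademacher (±1, probability ½) by
default because it preserves residual magnitudes exactly; Mammen two-point
and standard-normal weights are selectable. The scheme requires no repeated
measurements and is valid under both homoscedastic and heteroscedastic
noise. Resamples whose refit fails are redrawn so the requested resample
count is exact (redraw count logged); more than 20% failures aborts.
Default 5000 resamples; the tests and the acceptance script use 100–1000,
which is ample for SDs (bootstrap SE of an SD at B resamples is ≈
SD/√(2B)).

## Uncertainty propagation and bands

Parameter uncertainty propagates to the trajectory by the first-order delta
method without covariance terms:

    δMWF(x) = sqrt( Σᵢ (∂f/∂aᵢ|ₓ)² · (δaᵢ)² ).

Two facts about this estimator, both verified in the test suite:

1. **Its linearization is excellent.** Against the SD of curves under
   independent Gaussian parameter perturbations at the bootstrapped SDs it
   agrees to ~1% for study-like fits (tested at 15%).
2. **Neglecting covariances makes it conservative here.** Modified-Gompertz
   parameter estimates are intrinsically strongly correlated (empirically
   corr(α,δ) ≈ −0.97 and corr(β,γ) ≈ +0.94 at n=122, σ=0.012), and the
   correlations *reduce* curve variance; the no-covariance sum therefore
   overestimates the true mean-curve SD several-fold at every age. The
   covariance-aware alternative — the SD of the model evaluated over the
   raw bootstrap draws — is exposed as `bootstrap_curve_sd`.

Two band types must not be conflated:

* `confidence_band`: mean ± z·δMWF — uncertainty of the *mean* trajectory;
  it shrinks with cohort size and is **not** expected to contain individual
  measurements. A percentile-of-curves variant is available
  (`method='percentile'`).
* `prediction_band`: mean ± z·sqrt(mean_sd² + σ̂_resid²) with σ̂_resid the
  RSS-based residual SD — the band that should contain ~95% of individual
  measurements. Its mean-uncertainty term defaults to the covariance-aware
  `bootstrap_curve_sd` (`mean_uncertainty='bootstrap'`), because the
  conservative delta-method term (`'delta'`, also available) measurably
  over-covers (~98% rather than 95% at study conditions).

`empirical_coverage` closes the loop: it simulates replicate cohorts,
fits, bootstraps, builds the 95% prediction-scale band, and reports the
fraction of measurements inside — both for the fitted cohort itself (the
headline number) and for a fresh noise draw at the same ages. At study
conditions both land at ≈95%. Band membership uses a 1e-9 absolute slack
so that the degenerate noiseless case (zero-width band, points on the
fitted curve to solver precision) counts as fully covered.

## The voxel-wise atlas

Input volumes are smoothed with a 3 mm FWHM Gaussian kernel (σ =
FWHM/(2√(2 ln 2)) per axis, converted to voxel units, reflective
boundaries — total intensity conserved; FWHM below half a voxel is the
identity) *before* fitting. Each voxel whose across-age maximum MWF
reaches 0.02 — the same threshold that defines the white-matter analysis
mask — is fit independently (no spatial regularization) and bootstrapped;
everything else is excluded by `fit_mask` and carries NaN in all outputs.
Per-voxel seeds derive from the master seed and the voxel's linear index,
so results are independent of traversal order.

Querying the atlas at an age evaluates the model on the parameter fields
(mean MWF map) and applies the delta method per voxel (δMWF map). For
voxel-wise Z-maps the delta-method δMWF is the denominator the atlas
pairs with its mean map; note it shrinks as the normative cohort grows, so
a configuration hook accepts a prediction-scale SD map
(sqrt(δMWF² + σ²)) when Z should be calibrated against individual
variability. Ages outside the training span (70–1809 days for the default
cohort emulation) warn rather than error.

## Deviation statistics

`wm_mask` keeps voxels with MWF ≥ 0.02 (the boundary is in-mask).
`z_map` computes Z = (x − u)/s in-mask, drops zero-SD voxels with a logged
count, and flags |Z| ≥ 1.96 (the two-sided p = 0.05 normal critical
value). `group_paired_test` is a sign-flip permutation paired test on
voxel-wise differences: t = mean(d)/SE(d), null from random ±1 flips,
two-sided p = (1 + #{|t*| ≥ |t|})/(1 + B) — uncorrected, as voxel-wise
inference; the parametric paired-t p-value is reported alongside for
reference. Zero-variance voxels get p = 1 with a flag. No cluster-level or
other multiple-comparison correction is provided.

## Synthetic data

The generator emulates the study conditions the analysis assumes: a
122-subject cohort in 14 age groups spanning 70–1809 days (ages uniform
within each group's range; an option nudges draws to the tabulated group
means), regional modified-Gompertz trajectories with additive Gaussian
noise (default SD 0.012 MWF, the scatter scale of regional means about
their fitted curves; a heteroscedastic option scales SD with the mean),
and ellipsoidal voxel phantoms partitioned into contiguous Voronoi regions
with parameter fields drawn from plausibility ranges (α ∈ [0.05, 0.3],
β ∈ [0.5, 3], γ ∈ [0.003, 0.02]/day, δ ∈ [0, 5e-5]/day, ±5% smooth
within-region variation). The default regional truth (0.2, 1.5, 0.008,
1e-5) places the growth-rate peak near 190 days with a plateau near 0.2 —
a mid-range white-matter trajectory. These ranges are plausibility
choices calibrated to the observed scale of infant MWF data, not measured
constants. One master seed fixes ages, phantom, and all noise draws.

What the synthetic tests do **not** show: robustness to registration
error, motion artifacts and outliers, acquisition-dependent MWF bias,
spatially correlated noise, or real heteroscedasticity — the generator's
noise is i.i.d. within a volume, and volumes arrive pre-aligned. Passing
tests certify the statistical machinery under its own assumptions, not the
upstream imaging pipeline. The tabulated 36-month group range overlaps the
later groups' ranges; it is kept as tabulated, and the cohort validator
warns on (rather than rejects) overlapping ranges.

## Numerical notes

* Domain violations (fractional powers of negative bases in
  Bleasdale–Nelder/Richards/Stannard parameter combinations) raise a
  dedicated error naming the offending age elements; during optimization
  they are instead mapped to large residuals so LM steers away.
* Random streams (ages, noise, Rademacher weights, per-voxel seeds) are
  bit-reproducible for a given seed. Refit *outputs* are reproducible to
  solver precision but not guaranteed bit-identical across runs: numpy's
  vectorized transcendentals may round differently in the last ulp
  depending on temporary-buffer alignment, and ill-conditioned voxel
  refits can amplify that to ~1e-6 relative. Tests therefore compare
  fitted quantities at tight tolerances rather than bitwise.
* Fits with α outside (0, 1) or a non-monotone trajectory over the data
  range are legal (no constraints) but flagged by the post-fit sanity
  check in voxel-wise fitting only through their failure modes; the
  regional API reports them as-is.
* Problem sizes in the test suite (grids up to 8×8×4, 100–1000 resamples,
  50–100 replicates) are the package's desk-scale defaults for
  verification; the statistical conclusions they check are
  size-calibrated (binomial tolerance bands, SD ratios).

## Known limitations

* No BCa or studentized bootstrap intervals; no covariance-aware delta
  method (use `bootstrap_curve_sd` where covariances matter).
* Cross-sectional fitting only; repeated measures of one subject are
  treated as independent points.
* The Richards and general-logistic forms are fit as printed despite their
  parameter-role conflations; their rankings are interpretable but their
  parameters are not individually meaningful.
* Uncorrected voxel-wise inference only.
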