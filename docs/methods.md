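# Methods

## Structural model

Each of n subjects carries unobservable true values X (reference technique
A) and Y (candidate technique B). Observations are

    x = X + ϵ,    y = Y + δ,

with ϵ, δ independent of the true values and of each other, E[ϵ] = E[δ] = 0.
Because the errors average out, ȳ − x̄ is an unbiased estimate of the
structural bias Ȳ − X̄; this expectation identity is what lets functional
regressions on observed data test structural hypotheses. Replicate readings,
when present, are collapsed to per-subject means for every regression;
replicates enter the analysis only through the estimation of λ (below).
Subjects with any missing declared value are removed listwise — all three
tests are paired by subject — and every removal is logged.

## The error-variance ratio λ

λ = V[δ]/V[ϵ] (candidate over reference) equals 1 when the techniques are
equally precise and parameterizes the Deming regression. With rᵢ ≥ 2
replicates per technique it is estimated as the ratio of pooled
within-subject variances,

    λ̂ = [Σᵢⱼ (yᵢⱼ − ȳᵢ)² / Σᵢ(rᵢ−1)] / [Σᵢⱼ (xᵢⱼ − x̄ᵢ)² / Σᵢ(rᵢ−1)],

the standard repeated-measures correction. Without replicates λ defaults to
1 with a logged warning; a user-supplied value always overrides estimation.
Degenerate cases: zero within-subject variance on the reference side with
positive candidate variance makes λ undefined (an error); zero on both
sides falls back to 1, flagged. Swapping the techniques maps λ̂ → 1/λ̂
exactly.

## The three tests

**Test 1 — accuracy.** OLS of dᵢ = yᵢ − xᵢ on the centered covariate
xᵢ − x̄. Centering makes the intercept α̂ equal d̄ exactly, so the intercept
t-test (n − 2 df, via statsmodels OLS) is a test of equal structural means.
Residuals are assumed homoscedastic; no robust covariance option is offered
in this version. Conditional on a finite sample the covariate is centered
at x̄ rather than the population mean, which makes the test very slightly
liberal when the reference carries substantial measurement error (about
5.5% empirical size at the 5% level under the default simulation
conditions); this is a property of the published procedure, not of the
implementation.

**Test 2 — precision.** OLS of dᵢ on the sums uᵢ = xᵢ + yᵢ. Under the
structural model the population slope is zero iff λ = 1, and the slope
t-test is algebraically identical to the Pitman–Morgan correlation test of
ρ(x − y, x + y) = 0. The sign of the fitted slope matches the sign of
s_yy − s_xx. When all differences are identical there is nothing to test
and the p-value is reported as 1.

**Test 3 — bisector agreement.** Deming regression of y on x:

    β̂ = [(s_yy − λ s_xx) + √((s_yy − λ s_xx)² + 4 λ s_xy²)] / (2 s_xy),
    α̂ = ȳ − β̂ x̄,

taking the quadratic root whose sign matches s_xy (verified against the
λ → ∞ and λ → 0 OLS limits, a brute-force minimizer of the profiled
errors-in-variables objective Σ(yᵢ − α − βxᵢ)²/(λ + β²), and orthogonal
distance regression). Standard errors are leave-one-subject-out jackknife
(computed by vectorized moment downdates), with t reference on n − 2 df.
The joint null α = 0, β = 1 is tested with each parameter at level/2
(Bonferroni), preserving the family level; because α̂ and β̂ are strongly
negatively correlated the family decision is conservative (empirical size
≈ 3.4% at a nominal 5% under the null at n = 50). Exact-line data produce
zero jackknife SEs; the p-value is then 1 if the estimate equals its null
value and 0 otherwise.

## Bootstrap machinery

All graphical decisions come from one subject-level bootstrap design:
subjects are resampled with replacement (replicate blocks intact, so
within-subject error structure is preserved), the regression of interest is
refit, and

* the **band** is the pointwise 2.5th–97.5th percentile envelope of the
  refitted lines over a 100-point grid spanning the observed abscissa range
  (no extrapolation);
* the **ellipse** is centered at the mean bootstrap (slope, intercept)
  pair, shaped by their sample covariance, with squared radius equal to the
  empirical 95th percentile of the pairs' Mahalanobis distances —
  nonparametric throughout, rather than a χ²₂ quantile.

Percentile intervals (no bias correction/acceleration) match the
interpretation "the region containing 95% of resampled regressions".
Defaults: 2000 resamples, seeded; each of the three tests in one assessment
uses a distinct derived sub-seed so their resampling streams are
independent. Degenerate resamples (e.g. a resample with constant x) are
redrawn and counted; more than 10% redraws logs a warning. All outputs are
bit-reproducible given the seed.

Line-in-band feasibility is solved analytically: a line of slope m fits the
band iff max_g(lower(g) − m·g) ≤ min_g(upper(g) − m·g); intersecting that
intercept interval with a constraint interval gives the translated
decisions. Point-in-ellipse uses the closed region (boundary counts as
inside).

## Translation and the verdict

When the accuracy test finds a bias, the graphical precision and agreement
decisions are re-run in translated mode: the candidate horizontal line
(precision) or bisector-parallel line (agreement) may take any intercept
inside the *analytic 95% CI of the bias* — the interval reading is more
conservative than translating by the point estimate alone. The verdict is a
pure function of the per-test decision triples (analytic, graphical,
translated): when analytic and graphical decisions disagree — a discordance
attributable to bias — the graphical decision after translation governs.
Five categories: `strict_equivalence` (nothing rejects),
`equivalent_after_bias_correction` (only the bias; translated tests 2–3
pass), `precision_mismatch`, `agreement_mismatch`, `multiple_failures`.
A precision failure always flags the bisector verdict as uninterpretable:
the Deming geometry presumes comparable error variances. Classic limits of
agreement (d̄ ± 1.96·SD) appear in a comparison panel only and never feed
the verdict.

## Synthetic data

The generator draws true values X from Normal(μ = 100, σ = 15) by default
(uniform and symmetric two-point-mass options exist to exercise
non-normality, the latter being the adversarial shape for Chebyshev-bound
properties), applies the linear calibration Y = a + b·X, and adds Gaussian
errors with SDs (σ_ϵ, σ_δ), so the true λ is (σ_δ/σ_ϵ)². The default error
SD of 5 on both techniques mimics a physiological quantity measured with
roughly 5% relative error at the typical level. The generator reproduces
the structural model exactly — it does not emulate heteroscedastic
(level-dependent) errors, autocorrelation, outliers, digit preference or
non-Gaussian error shapes, so passing calibration and recovery tests speak
to the model's behavior under its own assumptions, not to robustness
against such features of real data. Truth records travel separately from
the generated MeasurementSet so production code never sees them.

## Problem sizes used in validation

The automated checks use desk-scale Monte Carlo: 1000 null datasets of
n = 50 for type-I calibration (each analytic statistic within 3 binomial
SEs of 5%; the Bonferroni family rate bounded above), 200 runs of n = 500
with duplicate readings for λ recovery (median relative error < 15%),
150 outer replications for band coverage, and a few hundred runs for power
checks. The acceptance script uses 20000 null simulations for a low-noise
estimate of the empirical size. These sizes give stable Monte-Carlo
estimates while keeping the whole suite fast.

## Known limitations

* Constant error variances are assumed; no weighted Deming or
  variance-stabilizing transforms (users may pre-transform their data).
* The analytic accuracy test is mildly liberal when the reference error is
  a sizable fraction of the between-subject spread (see above).
* Jackknife SEs for the Deming parameters follow common practice for this
  estimator but are not exact in small samples; the bootstrap remains the
  graphical authority.
* Decisions are rejection/non-rejection at a fixed level; no
  equivalence-margin (TOST) machinery, and non-rejection in small samples
  is weak evidence — plan sample sizes a priori.
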