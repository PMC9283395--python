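# Methods

This note documents the statistical model, the synthetic study generator,
the numerical choices behind the sampler and diagnostics, and what the
package's tests do and do not establish about real data.

## The two-level model and its assumptions

Let y_ij be the standardized fGCM concentration of sample j from individual
i, and ȳ_i the mean of individual i's standardized samples. The model has
two Gaussian likelihoods sharing one coefficient vector:

* Level 1 (individual baselines): ȳ_i ~ Normal(μ_i, τ₁), with
  μ_i = α + x_i'β a deterministic linear predictor in five time-invariant
  covariates — adult caregivers, age mates, number of samples, orphan
  status, non-natal group membership. τ₁ is a precision (1/variance).
* Level 2 (sampling events): y_ij ~ Normal(μ_ij, τ₂), with
  μ_ij = μ_i + z_ij'γ in eight time-varying covariates — age, lactating,
  hours the dung sat on the ground, time of day (fraction of the day),
  NDVI spatial mean, pregnancy, NDVI spatial SD, years since the mother's
  death (zero for nonorphans). An optional ninth coefficient adds
  strongylid fecal egg counts on the subset of samples that have them.

Two structural facts deserve emphasis, because they drive everything the
recovery experiments show:

1. **μ_i is deterministic.** There is no free random intercept; individual
   baselines are entirely explained by the five covariates plus the level-1
   noise term, and the observed per-individual means ȳ_i enter the model as
   data while μ_i simultaneously feeds level 2. The two levels therefore
   inform each other through the shared coefficients.
2. **Each y_ij appears in both likelihoods** (directly at level 2 and
   through ȳ_i at level 1). This "double use" is kept deliberately: the
   package reproduces the published model structure rather than a corrected
   random-effects formulation, and the recovery tooling quantifies the
   consequences (see Limitations).

All covariates and the response, binary columns included, are standardized
to mean 0 and sample SD 1 (n−1 denominator) before fitting, so every
coefficient is in response-SDs per covariate-SD. A guard in `fit` refuses
unstandardized inputs. Credible intervals are equal-tailed posterior
intervals; the report table flags coefficients whose 95% (and 50%) interval
strictly excludes zero.

## Priors

The analysis is meant to be prior-insensitive: Normal(0, sd 1000) on every
coefficient and Gamma(shape 0.001, rate 0.001) on both precisions — the
conventional diffuse choice in BUGS/JAGS-style modeling. `PriorSpec` exposes
all four hyperparameters; a sensitivity run is a one-line config change.

## Sampler

Given (τ₁, τ₂), stacking the level-1 rows [1, x_i, 0] and level-2 rows
[1, x_i, z_ij] makes the model linear-Gaussian in θ = (α, β, γ), whose full
conditional is multivariate normal; given θ, each precision has a Gamma full
conditional. `fit` is therefore an exact blocked Gibbs sampler:

1. θ | τ: precision Λ = τ₁A'A + τ₂B'B + prior precision; draw
   θ ~ Normal(Λ⁻¹(τ₁A'ȳ + τ₂B'y + prior term), Λ⁻¹) via Cholesky.
2. τ₁ | θ ~ Gamma(shape + I/2, rate + ½Σ(ȳ_i − μ_i)²), and analogously
   τ₂ with the level-2 residuals.

The Gram matrices are precomputed once, so one iteration costs a single
14×14 (or 15×15) Cholesky factorization; the full protocol — three chains of
100,000 iterations, 10,000 burn-in, no thinning — runs in well under a
minute on one CPU. No adaptation phase is needed for a Gibbs sampler; the
`n_adapt` setting is accepted for protocol fidelity and ignored. Chains are
initialized over-dispersed (coefficient jitter of SD 0.5, lognormal
precision jitter) from per-chain streams spawned off one root seed, so runs
are exactly reproducible. Degenerate designs are rejected before sampling:
a rank-revealing QR of the stacked design names the collinear columns.

Correctness is established against independent routes rather than by
self-consistency: a closed-form conjugate posterior on an intercept-only
instance with fixed precisions; dense-grid integration of the joint density
on a 3-individual/8-sample instance (the two precisions integrated
analytically through their Gamma conditionals); and a refit of the same
data, model and priors in rjags, which must agree in posterior means and
SDs.

## Diagnostics

`gelman_rubin` computes the corrected potential scale reduction factor on
unsplit post-burn-in chains: with within-chain variance W and between-chain
variance B, the pooled estimate is (n−1)/n·W + (1+1/m)·B/n, degrees-of-
freedom-adjusted by (d+3)/(d+1) with d estimated from the sampling variance
of the pooled estimate. This is the classic point estimate reported by
`coda::gelman.diag` (verified against it to 1e-8 in the tests); split-chain
and rank-normalized variants are deliberately out of scope. Identical
chains yield a value at (or for B = 0 slightly below) 1; the conventional
convergence threshold is 1.1.

`posterior_predictive_check` replicates, for every retained draw, the
level-1 vector ȳ^rep ~ Normal(μ_i, 1/τ₁) and the level-2 vector
y^rep ~ Normal(μ_ij, 1/τ₂), and reports four Bayesian p-values:
P(T(rep) ≥ T(obs)) with T the mean and the sample SD at each level
(inclusive comparison; ties have measure zero for continuous statistics).
Values near 0 or 1 indicate misfit. Level-1 replication is done directly
from the level-1 likelihood rather than by aggregating replicated level-2
data, matching the model's two explicit likelihoods. Replication noise is
seeded; computation is chunked so the draws × samples replicate matrix
never materializes at once.

## The synthetic study generator

The generator emulates the study design so every stage is testable offline:

* **Population** (defaults): 37 females, 25 orphans of whom 5 live in
  non-natal groups; caregivers on {0..4} weighted toward low counts;
  age mates on {0..8} with decreasing weights; ages uniform on 7–21 years;
  orphans' years-since-mother's-death positive and advancing with time,
  exactly zero for nonorphans.
* **Seasonality**: a smooth two-peaks-per-year greenness curve (amplitude
  0.13 around 0.42, index units) with small noise for the NDVI spatial
  mean, and a spatial SD proportional to the absolute rate of change of the
  smooth curve — resource patchiness peaks during green-up and brown-down.
  NDVI absolute level is irrelevant downstream because all covariates are
  standardized.
* **Sampling**: per individual, a sample count near 15 ± 4 (floor 2) placed
  over 396 days with at least 14 days between consecutive samples;
  pregnancy and lactation as persistent multi-month episodes; daylight
  collection times; exponential time-on-ground (mean 1 h); fecal egg counts
  Gamma-distributed with 10% missing.
* **Response**: the random-intercept analog of the fitted model,
  y* = α + x'β + η_i + z'γ + ε with η_i ~ Normal(0, σ1²) and
  ε ~ Normal(0, σ2²), coefficients defaulting to the reported estimates.
  y* is centered, scaled by its realized SD, and mapped to ng/g with center
  95.69 and SD 30.21, floored at 1 ng/g (the floor is essentially never
  active at these settings). The realized SD of y* (`response_scale`,
  ≈ 1.4 at the defaults) is recorded in the truth sidecar: after the
  pipeline re-standardizes the ng/g response, fitted coefficients live on
  the y*/sd(y*) scale, so recovery comparisons multiply posterior summaries
  by `response_scale` before comparing to the generative truth.
* **Contamination**: nine samples, each in a different individual (the
  individuals with the most samples, ties broken by id), displaced upward
  by 8 of that individual's sample SDs and flagged in a provenance column.
  Eight SDs, not a smaller displacement, because the screening statistic is
  internally studentized: a point displaced by k SDs among n samples
  reaches only about k(1−1/n)/sqrt(1+k²/n) internal SDs — at n = 15, k = 8
  gives ≈ 3.27, just clear of the 3-SD threshold, whereas k = 5 can never
  be caught below n ≈ 19.
* The noise SDs default to σ1 = 0.3, σ2 = 0.8 on the standardized scale —
  plausible magnitudes chosen once for the emulation (the study reports no
  comparable quantities), giving within-individual scatter that dominates
  between-individual scatter, as fGCM data typically show.

What the generator does **not** emulate: assay/extraction noise beyond the
Gaussian error term, spatial raster structure behind the NDVI summaries,
movement or social-network dynamics, autocorrelation within individuals
beyond the shared intercept, and skewed concentration distributions
(real fGCM data are right-skewed; the emulation is Gaussian on the
standardized scale). Tests passing on this emulation therefore validate
the pipeline's computations, not the biological adequacy of the model for
any particular dataset.

## Screening and standardization details

The outlier screen runs once, on the raw ng/g scale, per individual, with
mean and sample SD computed from all of that individual's samples including
the candidate; a sample is discarded iff |y − mean| > 3·SD strictly (ties
at exactly 3 SD are kept). Consequences documented and tested: the maximum
attainable internal deviation is (n−1)/√n SDs, so no sample can ever be
discarded from an individual with 10 or fewer samples; an individual with a
single sample has no defined SD and is an error. The per-individual sample
count covariate is recomputed *after* screening. For the fecal egg count
variant, rows with missing counts are dropped first and the reduced table
is re-standardized.

## Recovery experiments and calibration

`recovery_experiment` repeatedly generates a study with known truth, runs
the full pipeline (contamination, screening, design, fit), and reports
per-coefficient bias, RMSE, 95% interval coverage and sign agreement, with
estimates mapped back to the generator scale via `response_scale`.

At study scale with the reported coefficient values as truth, point
estimation is excellent — replicate-averaged recovered values land within
a few thousandths of the truth for the strong effects (non-natal group,
age mates, NDVI mean, NDVI SD), and their signs are recovered in every
replicate. Interval calibration is not uniform, and this is a property of
the model being reproduced, not of the sampler: because μ_i is
deterministic, the level-2 likelihood treats all ~500 samples as
independent evidence about individual-level coefficients, while in the
generator (and in any plausible real population) samples within an
individual are correlated through the shared intercept η_i. Credible
intervals for the individual-level block (and for covariates that vary
mostly between individuals, such as age and years-without-mother) are
therefore too narrow, with measured 95% coverage as low as ~0.5–0.75
depending on σ1; sample-level covariates with real within-individual
variation (NDVI mean/SD, reproductive state, ground time, time of day) are
well calibrated (coverage ≈ 0.9–1.0). Shrinking σ1 toward zero removes the
clustering and restores coverage, confirming the mechanism. Users drawing
individual-level conclusions from this model class should treat its
credible intervals for those coefficients as optimistic; a random-intercept
extension would fix this but is outside this package's scope, which is to
reproduce the published structure faithfully.

The posterior-predictive checks are calibrated in the regime the model
itself defines: fitting data generated from the sample-level law (with
individual means derived from it, exactly as the design assembles them)
yields all four p-values comfortably inside (0.05, 0.95) in ≥ 18/20
replicates.

## Problem sizes and numerical choices

Tests and the acceptance script use the full study scale (37 individuals,
~500–550 samples) throughout; the fitting protocol is the full 3 × 100,000
where the protocol itself is under test and a scaled-down 3 × 4,000–6,000
(burn-in 500–600) for replicate experiments, where the conjugate sampler's
effectively independent draws make longer chains unnecessary. Replicate
counts are 20 for calibration tests and 40 in the acceptance script.
Sums of squares in the Gibbs updates are clipped at zero against negative
rounding; the standardization guard uses an absolute tolerance of 1e-6;
the collinearity check uses a QR tolerance of max(m,n)·eps·max|R_kk|.
Equal-tailed quantiles are computed on chains pooled after burn-in.

## Known limitations

* Interval undercoverage for individual-level coefficients under clustered
  data, as quantified above — inherent to the deterministic-μ_i structure.
* The Gaussian emulation cannot reproduce order statistics (minima/maxima)
  or skewness of real concentration data; descriptive checks target means,
  SDs and counts only.
* No effective-sample-size, autocorrelation or information-criterion
  computations; convergence reporting is the corrected Rc point estimate
  only.
* The screen's inclusion convention (candidate included in its own mean/SD)
  is an assumption; with per-individual sample counts around 15 it is
  conservative, and the ≤10-sample impossibility bound documents exactly
  how conservative.
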