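# fgcmbayes

Hierarchical Bayesian analysis of fecal glucocorticoid metabolite (fGCM)
concentrations from longitudinally sampled wild animals.

fGCMs are breakdown products of glucocorticoid stress hormones measured in
dung (ng per g dry weight) — a noninvasive window onto adrenal activity in
wildlife. In the study design this package implements, female elephants —
orphans and nonorphans living in natal or non-natal family groups — were
each sampled repeatedly over about thirteen months, at least two weeks
apart, together with social covariates (adult caregivers, age mates),
reproductive state, satellite-derived vegetation indices (NDVI mean and
spatial SD), and strongylid fecal egg counts. The scientific question is how
social context and environment relate to baseline and sample-level
glucocorticoid levels.

## The model

After screening and standardization, the analysis is a two-level
hierarchical Bayesian regression. Level 1 relates each individual's mean
standardized concentration to time-invariant covariates:

    ȳᵢ ~ Normal(μᵢ, τ₁),   μᵢ = α + β₁fᵢ + β₂mᵢ + β₃nᵢ + β₄oᵢ + β₅aᵢ

(f = adult caregivers, m = age mates, n = number of samples, o = orphan
status, a = non-natal group; τ₁ a precision). Level 2 uses μᵢ as the
intercept for every sample from individual i:

    yᵢⱼ ~ Normal(μᵢⱼ, τ₂),  μᵢⱼ = μᵢ + γ₁gᵢⱼ + γ₂lᵢⱼ + γ₃sⱼ + γ₄tⱼ + γ₅vⱼ + γ₆pᵢⱼ + γ₇zⱼ + γ₈bᵢⱼ

(g = age, l = lactating, s = hours on the ground before collection,
t = time of day, v = NDVI mean, p = pregnant, z = NDVI spatial SD, b = years
since the mother's death; an optional γ₉ adds fecal egg counts on the
subset of samples that have them). Because μᵢ is a deterministic function of
the coefficients, the joint model is linear-Gaussian given the precisions
and conditionally conjugate given the coefficients; `fgcmbayes.model.fit`
samples it with an exact blocked Gibbs sampler (multivariate-normal update
for all coefficients jointly, Gamma updates for τ₁ and τ₂), three chains of
100,000 iterations with 10,000 burn-in by default. Convergence is checked
with the corrected Gelman–Rubin factor (Rc < 1.1) and model fit with
posterior-predictive Bayesian p-values for the mean and SD at each level.

The package also ships a synthetic study generator (population, bimodal
seasonal NDVI series, repeated sampling with outlier contamination) so the
whole pipeline is testable without any external data, plus the screening
rule of the original analysis: a sample is discarded when it lies more than
three sample SDs from its own individual's mean concentration.

## Worked example

```bash
fgcm-pipeline run --seed 1 --out demo_run
```

simulates the default study (37 subjects, ~540 samples, 9 planted
outliers), screens it, fits the model at the full protocol and writes the
report table, printing artifacts and then (from `demo_run/summary.csv`):

```
parameter                 covariate  estimate  ci95_lower  ci95_upper  flag95
    alpha                 intercept     0.033      -0.012       0.078   False
    beta5      with non-natal group    -0.297      -0.347      -0.247    True
    beta3         number of samples    -0.157      -0.205      -0.108    True
    beta1          adult caregivers    -0.156      -0.202      -0.109    True
    beta2                 age mates    -0.118      -0.166      -0.071    True
    beta4             orphan status     0.131       0.064       0.199    True
   gamma5                 mean NDVI    -0.472      -0.522      -0.423    True
   gamma2                 lactating    -0.047      -0.099       0.006   False
   gamma8         years without mom    -0.001      -0.071       0.069   False
   gamma4               time of day     0.023      -0.027       0.073   False
   gamma3 time sample sat on ground     0.032      -0.019       0.082   False
   gamma1                       age     0.055      -0.001       0.110   False
   gamma6                 pregnancy     0.094       0.043       0.145    True
   gamma7   NDVI standard deviation     0.585       0.536       0.635    True
     tau1         level-1 precision    12.618       7.461      19.127    True
     tau2         level-2 precision     3.089       2.715       3.485    True
```

Estimates are in SDs of the standardized response per SD of each covariate;
`flag95` marks coefficients whose 95% credible interval excludes zero.
Here the strong negative mean-NDVI effect (more food, lower glucocorticoids)
and the strong positive NDVI-SD effect (patchier food, higher
glucocorticoids) planted by the generator are recovered with the correct
signs and intervals excluding zero. On the generator scale (multiplying by
the recorded response scale) gamma5 ≈ −0.69 and gamma7 ≈ 0.79, the planted
truths. `demo_run/convergence.json` reports every Rc below 1.1 and
`demo_run/ppc.json` reports all four Bayesian p-values mid-range
(0.45–0.59), i.e. no evidence of misfit.

The same workflow is available as a library (`fgcmbayes.run`,
`fgcmbayes.recovery_experiment`) and as stage-by-stage subcommands
(`simulate`, `preprocess`, `fit`, `diagnose`, `report`, `recover`).

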