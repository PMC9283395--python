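"""Tests of the two-level model: log posterior, Gibbs sampler, summaries.

The sampler's external oracle here is rjags (JAGS via R), i.e. the modeling
environment the two-level structure originates from: the same model, priors
and data fitted by an entirely independent sampler must give the same
posterior.  Closed-form and grid oracles live in the acceptance suite.
"""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fgcmbayes as fb
from fgcmbayes.errors import CollinearityError, ConfigurationError, ValidationError
from fgcmbayes.model import ModelState

from conftest import make_small_inputs


def scipy_log_posterior(state, inputs, priors):
    """Independent term-by-term oracle using scipy distributions."""
    mu_i = state.alpha + inputs.X @ state.beta
    mu_ij = mu_i[inputs.sample_index] + inputs.Z @ state.gamma
    lp = stats.norm.logpdf(inputs.ybar, mu_i, 1.0 / np.sqrt(state.tau1)).sum()
    lp += stats.norm.logpdf(inputs.y, mu_ij, 1.0 / np.sqrt(state.tau2)).sum()
    theta = np.concatenate([[state.alpha], state.beta, state.gamma])
    lp += stats.norm.logpdf(theta, priors.coef_prior_mean, priors.coef_prior_sd).sum()
    lp += stats.gamma.logpdf(
        [state.tau1, state.tau2], a=priors.precision_shape, scale=1.0 / priors.precision_rate
    ).sum()
    return float(lp)


class TestLogPosterior:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scalar_density_sum(self, seed):
        inputs = make_small_inputs(seed=seed, I=3, N=7, n_beta=1, n_gamma=1)
        rng = np.random.default_rng(seed)
        state = ModelState(
            alpha=rng.normal(),
            beta=rng.normal(size=1),
            gamma=rng.normal(size=1),
            tau1=float(rng.uniform(0.5, 3.0)),
            tau2=float(rng.uniform(0.5, 3.0)),
        )
        priors = fb.PriorSpec()
        assert fb.log_posterior(state, inputs, priors) == pytest.approx(
            scipy_log_posterior(state, inputs, priors), abs=1e-10
        )

    def test_zero_state_unit_precision_closed_form(self):
        inputs = make_small_inputs(seed=3, I=4, N=12, n_beta=1, n_gamma=1)
        state = ModelState(alpha=0.0, beta=np.zeros(1), gamma=np.zeros(1), tau1=1.0, tau2=1.0)
        priors = fb.PriorSpec()
        I, N = inputs.n_individuals, inputs.n_samples
        likelihood = (
            -I / 2 * np.log(2 * np.pi) - (inputs.ybar**2).sum() / 2
            - N / 2 * np.log(2 * np.pi) - (inputs.y**2).sum() / 2
        )
        log_prior = stats.norm.logpdf(np.zeros(3), 0, priors.coef_prior_sd).sum() + 2 * stats.gamma.logpdf(
            1.0, a=priors.precision_shape, scale=1.0 / priors.precision_rate
        )
        assert fb.log_posterior(state, inputs, priors) == pytest.approx(likelihood + log_prior, abs=1e-10)

    def test_nonpositive_precision_is_minus_infinity(self):
        inputs = make_small_inputs(seed=4)
        state = ModelState(alpha=0.0, beta=np.zeros(1), gamma=np.zeros(1), tau1=1.0, tau2=0.0)
        assert fb.log_posterior(state, inputs, fb.PriorSpec()) == -np.inf

    def test_dimension_mismatch_rejected(self):
        inputs = make_small_inputs(seed=5, n_beta=2)
        state = ModelState(alpha=0.0, beta=np.zeros(1), gamma=np.zeros(1), tau1=1.0, tau2=1.0)
        with pytest.raises(ValidationError):
            fb.log_posterior(state, inputs, fb.PriorSpec())


class TestFit:
    def test_no_retained_draws_rejected(self, study_inputs):
        with pytest.raises(ConfigurationError, match="n_burnin"):
            fb.fit(study_inputs, mcmc=fb.MCMCConfig(n_iterations=1000, n_burnin=1000))

    def test_deterministic_given_seed(self):
        inputs = make_small_inputs(seed=6, I=8, N=40)
        mcmc = fb.MCMCConfig(n_chains=2, n_iterations=500, n_burnin=100, seed=9)
        a = fb.fit(inputs, mcmc=mcmc, check_standardized=False)
        b = fb.fit(inputs, mcmc=mcmc, check_standardized=False)
        assert np.array_equal(a.draws, b.draws)
        c = fb.fit(
            inputs,
            mcmc=fb.MCMCConfig(n_chains=2, n_iterations=500, n_burnin=100, seed=10),
            check_standardized=False,
        )
        assert not np.array_equal(a.draws, c.draws)
        # chains within one fit are distinct
        assert not np.array_equal(a.draws[0], a.draws[1])

    def test_unstandardized_inputs_refused(self):
        inputs = make_small_inputs(seed=7)
        shifted = fb.ModelInputs(
            individual_index=inputs.individual_index,
            X=inputs.X + 1.0,
            ybar=inputs.ybar,
            sample_index=inputs.sample_index,
            Z=inputs.Z,
            y=inputs.y,
            standardization=inputs.standardization,
            level1_names=inputs.level1_names,
            level2_names=inputs.level2_names,
        )
        with pytest.raises(ValidationError, match="standardize"):
            fb.fit(shifted, mcmc=fb.MCMCConfig(n_iterations=200, n_burnin=50))

    def test_collinear_design_names_columns(self):
        inputs = make_small_inputs(seed=8, n_gamma=2)
        Z = inputs.Z.copy()
        Z[:, 1] = Z[:, 0]
        dup = fb.ModelInputs(
            individual_index=inputs.individual_index,
            X=inputs.X,
            ybar=inputs.ybar,
            sample_index=inputs.sample_index,
            Z=Z,
            y=inputs.y,
            standardization=inputs.standardization,
            level1_names=inputs.level1_names,
            level2_names=("z0", "z0_copy"),
        )
        with pytest.raises(CollinearityError, match="gamma"):
            fb.fit(dup, mcmc=fb.MCMCConfig(n_iterations=200, n_burnin=50), check_standardized=False)

    def test_tight_prior_dominates_posterior(self):
        """With a very informative coefficient prior the posterior collapses
        onto it (prior-dominance moment check)."""
        inputs = make_small_inputs(seed=9, I=5, N=20)
        priors = fb.PriorSpec(coef_prior_mean=0.0, coef_prior_sd=0.01)
        draws = fb.fit(
            inputs,
            priors=priors,
            mcmc=fb.MCMCConfig(n_chains=2, n_iterations=4000, n_burnin=500, seed=3),
            check_standardized=False,
        )
        pooled = draws.pooled()
        coef = pooled[:, : len(draws.names) - 2]
        assert np.abs(coef.mean(axis=0)).max() < 0.01
        assert coef.std(axis=0, ddof=1).max() < 0.012

    def test_row_permutation_leaves_posterior_unchanged(self):
        """Permuting sample rows together with their individual mapping is a
        relabeling; posterior summaries agree to numerical noise."""
        inputs = make_small_inputs(seed=10, I=6, N=30, n_beta=1, n_gamma=2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(inputs.n_samples)
        permuted = fb.ModelInputs(
            individual_index=inputs.individual_index,
            X=inputs.X,
            ybar=inputs.ybar,
            sample_index=inputs.sample_index[perm],
            Z=inputs.Z[perm],
            y=inputs.y[perm],
            standardization=inputs.standardization,
            level1_names=inputs.level1_names,
            level2_names=inputs.level2_names,
        )
        mcmc = fb.MCMCConfig(n_chains=2, n_iterations=3000, n_burnin=500, seed=4)
        a = fb.fit(inputs, mcmc=mcmc, check_standardized=False).pooled().mean(axis=0)
        b = fb.fit(permuted, mcmc=mcmc, check_standardized=False).pooled().mean(axis=0)
        assert np.allclose(a, b, atol=1e-6)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_sampler_matches_rjags_reference(tmp_path):
    """Dual-route check: the same model, priors and data fitted with rjags
    must give the same posterior means and SDs as the blocked Gibbs sampler."""
    inputs = make_small_inputs(seed=17, I=10, N=60, n_beta=2, n_gamma=3)
    draws = fb.fit(
        inputs,
        mcmc=fb.MCMCConfig(n_chains=3, n_iterations=22000, n_burnin=2000, seed=7),
        check_standardized=False,
    )
    ours = fb.summarize(draws, table_order=False)

    pd.DataFrame(inputs.X).to_csv(tmp_path / "X.csv", index=False)
    pd.DataFrame(inputs.Z).to_csv(tmp_path / "Z.csv", index=False)
    pd.DataFrame({"y": inputs.y, "ind": inputs.sample_index + 1}).to_csv(
        tmp_path / "y.csv", index=False
    )
    pd.DataFrame({"ybar": inputs.ybar}).to_csv(tmp_path / "ybar.csv", index=False)
    script = textwrap.dedent(
        """
        suppressMessages(library(rjags))
        args <- commandArgs(trailingOnly = TRUE)
        dir <- args[1]
        X <- as.matrix(read.csv(file.path(dir, "X.csv")))
        Z <- as.matrix(read.csv(file.path(dir, "Z.csv")))
        yd <- read.csv(file.path(dir, "y.csv"))
        ybar <- read.csv(file.path(dir, "ybar.csv"))$ybar
        model_string <- "
        model {
          for (i in 1:I) {
            mu[i] <- alpha + inprod(X[i,], beta)
            ybar[i] ~ dnorm(mu[i], tau1)
          }
          for (j in 1:N) {
            muij[j] <- mu[ind[j]] + inprod(Z[j,], gamma)
            y[j] ~ dnorm(muij[j], tau2)
          }
          alpha ~ dnorm(0, 1.0E-6)
          for (k in 1:P) { beta[k] ~ dnorm(0, 1.0E-6) }
          for (k in 1:Q) { gamma[k] ~ dnorm(0, 1.0E-6) }
          tau1 ~ dgamma(0.001, 0.001)
          tau2 ~ dgamma(0.001, 0.001)
        }"
        data <- list(I = length(ybar), N = nrow(yd), P = ncol(X), Q = ncol(Z),
                     X = X, Z = Z, y = yd$y, ind = yd$ind, ybar = ybar)
        set.seed(1)
        jm <- jags.model(textConnection(model_string), data = data,
                         n.chains = 3, n.adapt = 1000, quiet = TRUE)
        update(jm, 2000, progress.bar = "none")
        s <- coda.samples(jm, c("alpha", "beta", "gamma", "tau1", "tau2"),
                          n.iter = 20000, progress.bar = "none")
        m <- summary(s)$statistics
        write.csv(data.frame(param = rownames(m), mean = m[, "Mean"], sd = m[, "SD"]),
                  file.path(dir, "rjags.csv"), row.names = FALSE)
        """
    )
    (tmp_path / "ref.R").write_text(script)
    subprocess.run(
        ["Rscript", str(tmp_path / "ref.R"), str(tmp_path)],
        check=True,
        capture_output=True,
        timeout=300,
    )
    ref = pd.read_csv(tmp_path / "rjags.csv").set_index("param")
    mapping = {
        "alpha": "alpha",
        "beta[1]": "beta1", "beta[2]": "beta2",
        "gamma[1]": "gamma1", "gamma[2]": "gamma2", "gamma[3]": "gamma3",
        "tau1": "tau1", "tau2": "tau2",
    }
    for jags_name, our_name in mapping.items():
        ref_mean = ref.loc[jags_name, "mean"]
        ref_sd = ref.loc[jags_name, "sd"]
        if our_name.startswith("tau"):
            assert ours.loc[our_name, "mean"] == pytest.approx(ref_mean, rel=0.1), our_name
        else:
            assert ours.loc[our_name, "mean"] == pytest.approx(ref_mean, abs=0.02), our_name
        assert ours.loc[our_name, "sd"] == pytest.approx(ref_sd, rel=0.1), our_name


class TestSummarize:
    def test_constant_draws(self):
        draws = fb.PosteriorDraws(
            draws=np.full((2, 50, 1), 2.0), names=("alpha",), config=fb.MCMCConfig()
        )
        with pytest.warns(UserWarning):
            s = fb.summarize(draws)
        assert s.loc["alpha", ["mean", "q2.5", "q25", "q75", "q97.5"]].tolist() == [2.0] * 5
        assert bool(s.loc["alpha", "flag95"]) and bool(s.loc["alpha", "flag50"])

    def test_standard_normal_interval(self):
        rng = np.random.default_rng(1)
        draws = fb.PosteriorDraws(
            draws=rng.standard_normal((1, 100_000, 1)), names=("gamma1",), config=fb.MCMCConfig()
        )
        s = fb.summarize(draws)
        assert s.loc["gamma1", "q2.5"] == pytest.approx(-1.96, abs=0.05)
        assert s.loc["gamma1", "q97.5"] == pytest.approx(1.96, abs=0.05)
        assert not s.loc["gamma1", "flag95"]

    def test_interval_excluding_zero_flags_significant(self):
        # an all-negative interval like (-0.81, -0.01) marks significance
        draws = fb.PosteriorDraws(
            draws=np.linspace(-0.81, -0.01, 2000).reshape(1, 2000, 1),
            names=("beta5",),
            config=fb.MCMCConfig(),
        )
        s = fb.summarize(draws)
        assert bool(s.loc["beta5", "flag95"])

    def test_quantiles_nested_and_sorted_blocks(self, study_fit):
        s = fb.summarize(study_fit)
        assert (s["q2.5"] <= s["q25"]).all()
        assert (s["q25"] <= s["q75"]).all()
        assert (s["q75"] <= s["q97.5"]).all()
        beta_block = [n for n in s.index if n.startswith("beta")]
        assert beta_block == list(s.loc[beta_block].sort_values("mean").index)

    def test_empty_draws_rejected(self):
        draws = fb.PosteriorDraws(
            draws=np.empty((1, 0, 1)), names=("alpha",), config=fb.MCMCConfig()
        )
        with pytest.raises(ValidationError):
            fb.summarize(draws)
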