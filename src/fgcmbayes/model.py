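"""Two-level hierarchical Bayesian regression of fGCM concentrations.

Level 1 models each individual's mean standardized concentration:

    ybar_i ~ Normal(mu_i, 1/tau1),   mu_i = alpha + x_i' beta,

and level 2 models every sample, with the individual's level-1 linear
predictor as its intercept:

    y_ij ~ Normal(mu_ij, 1/tau2),    mu_ij = mu_i + z_ij' gamma.

tau1 and tau2 are precisions.  Both likelihood contributions are retained
exactly as stated — ybar_i is data at level 1 while mu_i feeds level 2 — so
the two levels inform one another through the shared coefficients.  Because
mu_i is a deterministic function of (alpha, beta), the joint model is linear-
Gaussian in the stacked coefficient vector theta = (alpha, beta, gamma) given
the precisions, and conditionally conjugate given theta.  ``fit`` therefore
uses a blocked Gibbs sampler whose full conditionals are exact:

* theta | tau1, tau2: multivariate normal from the precision-weighted
  combination of the level-1 rows [1, x_i, 0], the level-2 rows
  [1, x_i, z_ij] and the Normal prior;
* tau1 | theta ~ Gamma(shape + I/2, rate + SSR1/2);
* tau2 | theta ~ Gamma(shape + N/2, rate + SSR2/2).

No adaptation is needed; the ``n_adapt`` setting is accepted for protocol
fidelity and ignored.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, qr, solve_triangular

from .errors import CollinearityError, ConfigurationError, ValidationError
from .preprocess import ModelInputs

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "ModelState",
    "PosteriorDraws",
    "log_posterior",
    "fit",
    "summarize",
    "COVARIATE_LABELS",
]

#: Human-readable covariate labels for report tables.
COVARIATE_LABELS = {
    "alpha": "intercept",
    "beta1": "adult caregivers",
    "beta2": "age mates",
    "beta3": "number of samples",
    "beta4": "orphan status",
    "beta5": "with non-natal group",
    "gamma1": "age",
    "gamma2": "lactating",
    "gamma3": "time sample sat on ground",
    "gamma4": "time of day",
    "gamma5": "mean NDVI",
    "gamma6": "pregnancy",
    "gamma7": "NDVI standard deviation",
    "gamma8": "years without mom",
    "gamma9": "strongylid fecal egg count",
    "tau1": "level-1 precision",
    "tau2": "level-2 precision",
}


@dataclass(frozen=True)
class PriorSpec:
    """Diffuse conjugate priors: Normal on coefficients, Gamma on precisions."""

    coef_prior_mean: float = 0.0
    coef_prior_sd: float = 1000.0
    precision_shape: float = 0.001
    precision_rate: float = 0.001

    def validate(self) -> None:
        if self.coef_prior_sd <= 0:
            raise ConfigurationError("coef_prior_sd must be > 0")
        if self.precision_shape <= 0 or self.precision_rate <= 0:
            raise ConfigurationError("precision shape and rate must be > 0")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler protocol; defaults follow the study (3 × 100,000, 10,000 burn-in)."""

    n_chains: int = 3
    n_iterations: int = 100_000
    n_adapt: int = 1000
    n_burnin: int = 10_000
    thin: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_chains < 1:
            raise ConfigurationError("n_chains must be >= 1")
        if self.n_burnin + 1 >= self.n_iterations:
            raise ConfigurationError(
                f"n_burnin={self.n_burnin} leaves no retained draws out of "
                f"n_iterations={self.n_iterations}"
            )
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")


@dataclass
class ModelState:
    """One point in parameter space, with the deterministic linear predictors."""

    alpha: float
    beta: np.ndarray
    gamma: np.ndarray
    tau1: float
    tau2: float

    def mu_i(self, inputs: ModelInputs) -> np.ndarray:
        return self.alpha + inputs.X @ self.beta

    def mu_ij(self, inputs: ModelInputs) -> np.ndarray:
        return self.mu_i(inputs)[inputs.sample_index] + inputs.Z @ self.gamma


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained MCMC draws: array of shape (n_chains, n_kept, n_params)."""

    draws: np.ndarray
    names: tuple[str, ...]
    config: MCMCConfig

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]

    def pooled(self) -> np.ndarray:
        """All chains concatenated: shape (n_chains * n_kept, n_params)."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def parameter(self, name: str) -> np.ndarray:
        """Per-chain draws of one parameter: shape (n_chains, n_kept)."""
        return self.draws[:, :, self.names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        """Long table with chain and iteration columns (text-serializable)."""
        n_c, n_k, _ = self.draws.shape
        frame = pd.DataFrame(self.pooled(), columns=list(self.names))
        frame.insert(0, "iteration", np.tile(np.arange(n_k), n_c))
        frame.insert(0, "chain", np.repeat(np.arange(n_c), n_k))
        return frame

    def to_inference_data(self):
        """Convert to an :class:`arviz.InferenceData` for downstream tooling."""
        import arviz as az

        return az.from_dict({name: self.parameter(name) for name in self.names})

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, config: MCMCConfig | None = None) -> "PosteriorDraws":
        names = tuple(c for c in frame.columns if c not in ("chain", "iteration"))
        chains = sorted(frame["chain"].unique())
        arr = np.stack([frame.loc[frame["chain"] == c, list(names)].to_numpy() for c in chains])
        return cls(draws=arr, names=names, config=config or MCMCConfig())


def _coef_names(n_beta: int, n_gamma: int) -> tuple[str, ...]:
    return (
        ("alpha",)
        + tuple(f"beta{k + 1}" for k in range(n_beta))
        + tuple(f"gamma{k + 1}" for k in range(n_gamma))
    )


def _stacked_designs(inputs: ModelInputs) -> tuple[np.ndarray, np.ndarray]:
    """Level-1 rows [1, x_i, 0] and level-2 rows [1, x_i, z_ij] for theta."""
    I = inputs.n_individuals
    n_beta, n_gamma = inputs.X.shape[1], inputs.Z.shape[1]
    A = np.hstack([np.ones((I, 1)), inputs.X, np.zeros((I, n_gamma))])
    B = np.hstack(
        [np.ones((inputs.n_samples, 1)), inputs.X[inputs.sample_index], inputs.Z]
    )
    return A, B


def log_posterior(state: ModelState, inputs: ModelInputs, priors: PriorSpec) -> float:
    """Log posterior density (up to nothing — all normalizing constants kept).

    Returns −inf for non-positive precisions so gradient-free samplers can
    reject rather than raise.
    """
    priors.validate()
    if state.beta.shape != (inputs.X.shape[1],) or state.gamma.shape != (inputs.Z.shape[1],):
        raise ValidationError("state dimensions do not match inputs")
    if state.tau1 <= 0 or state.tau2 <= 0:
        return -math.inf

    mu_i = state.mu_i(inputs)
    mu_ij = state.mu_ij(inputs)

    def _normal_logpdf(x: np.ndarray, mean: np.ndarray, var: float) -> float:
        return float(-0.5 * np.sum((x - mean) ** 2) / var - 0.5 * x.size * math.log(2 * math.pi * var))

    lp = _normal_logpdf(inputs.ybar, mu_i, 1.0 / state.tau1)
    lp += _normal_logpdf(inputs.y, mu_ij, 1.0 / state.tau2)

    theta = np.concatenate([[state.alpha], state.beta, state.gamma])
    lp += _normal_logpdf(theta, np.full(theta.size, priors.coef_prior_mean), priors.coef_prior_sd**2)
    a, b = priors.precision_shape, priors.precision_rate
    for tau in (state.tau1, state.tau2):
        lp += a * math.log(b) - math.lgamma(a) + (a - 1) * math.log(tau) - b * tau
    return lp


def _check_standardized(inputs: ModelInputs) -> None:
    for name, mat in (("X", inputs.X), ("Z", inputs.Z), ("y", inputs.y.reshape(-1, 1))):
        cols = np.atleast_2d(mat.T)
        if mat.size == 0:
            continue
        if not np.allclose(cols.mean(axis=1), 0.0, atol=1e-6):
            raise ValidationError(f"{name} is not centered; standardize inputs before fitting")
        if not np.allclose(cols.std(axis=1, ddof=1), 1.0, atol=1e-6):
            raise ValidationError(f"{name} is not scaled to unit SD; standardize inputs before fitting")


def _check_collinearity(A: np.ndarray, B: np.ndarray, names: tuple[str, ...]) -> None:
    M = np.vstack([A, B])
    _, R, piv = qr(M, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(M.shape) * np.finfo(float).eps * diag.max()
    bad = [names[piv[k]] for k in range(len(diag)) if diag[k] < tol]
    if bad:
        raise CollinearityError(
            "combined design matrix is singular; offending column(s): " + ", ".join(bad)
        )


def fit(
    inputs: ModelInputs,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    fixed_precisions: tuple[float, float] | None = None,
    check_standardized: bool = True,
) -> PosteriorDraws:
    """Sample the joint posterior by blocked Gibbs.

    Parameters
    ----------
    inputs
        Standardized design matrices from :func:`fgcmbayes.preprocess.build_design`.
    priors, mcmc
        Prior hyperparameters and the chain protocol.
    fixed_precisions
        Optional (tau1, tau2) to hold fixed instead of Gibbs-updating them;
        used by conjugate oracle checks.
    check_standardized
        Refuse inputs whose columns are not mean-0 / SD-1 (pipeline guard).

    Returns retained post-burn-in draws for every chain; deterministic given
    ``mcmc.seed``.
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or MCMCConfig()
    priors.validate()
    mcmc.validate()
    inputs.validate()
    if check_standardized:
        _check_standardized(inputs)

    n_beta, n_gamma = inputs.X.shape[1], inputs.Z.shape[1]
    coef_names = _coef_names(n_beta, n_gamma)
    d = len(coef_names)
    A, B = _stacked_designs(inputs)
    _check_collinearity(A, B, coef_names)

    G1, G2 = A.T @ A, B.T @ B
    a1, a2 = A.T @ inputs.ybar, B.T @ inputs.y
    yty1 = float(inputs.ybar @ inputs.ybar)
    yty2 = float(inputs.y @ inputs.y)
    I, N = inputs.n_individuals, inputs.n_samples

    prior_prec = np.eye(d) / priors.coef_prior_sd**2
    prior_rhs = np.full(d, priors.coef_prior_mean) / priors.coef_prior_sd**2
    shape, rate = priors.precision_shape, priors.precision_rate

    n_kept = (mcmc.n_iterations - mcmc.n_burnin) // mcmc.thin
    names = coef_names + ("tau1", "tau2")
    out = np.empty((mcmc.n_chains, n_kept, d + 2))

    root = np.random.SeedSequence(mcmc.seed)
    for chain, child in enumerate(root.spawn(mcmc.n_chains)):
        rng = np.random.default_rng(child)
        # Over-dispersed starts: zero coefficients plus jitter, unit precisions
        # times a lognormal factor per chain.
        theta = rng.normal(0.0, 0.5, size=d)
        if fixed_precisions is None:
            tau1 = float(np.exp(rng.normal(0.0, 0.5)))
            tau2 = float(np.exp(rng.normal(0.0, 0.5)))
        else:
            tau1, tau2 = map(float, fixed_precisions)
            if tau1 <= 0 or tau2 <= 0:
                raise ConfigurationError("fixed precisions must be > 0")

        kept = 0
        for it in range(mcmc.n_iterations):
            # theta | tau
            Lam = tau1 * G1 + tau2 * G2 + prior_prec
            rhs = tau1 * a1 + tau2 * a2 + prior_rhs
            L = cholesky(Lam, lower=True)
            mean = cho_solve((L, True), rhs)
            theta = mean + solve_triangular(L.T, rng.standard_normal(d), lower=False)

            if fixed_precisions is None:
                # tau | theta
                ssr1 = max(yty1 - 2.0 * theta @ a1 + theta @ G1 @ theta, 0.0)
                ssr2 = max(yty2 - 2.0 * theta @ a2 + theta @ G2 @ theta, 0.0)
                tau1 = rng.gamma(shape + 0.5 * I, 1.0 / (rate + 0.5 * ssr1))
                tau2 = rng.gamma(shape + 0.5 * N, 1.0 / (rate + 0.5 * ssr2))

            if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0:
                out[chain, kept, :d] = theta
                out[chain, kept, d] = tau1
                out[chain, kept, d + 1] = tau2
                kept += 1

    return PosteriorDraws(draws=out, names=names, config=mcmc)


def summarize(draws: PosteriorDraws, table_order: bool = True) -> pd.DataFrame:
    """Posterior means, equal-tailed 95%/50% intervals and exclusion flags.

    ``flag95``/``flag50`` mark parameters whose respective interval strictly
    excludes zero.  With ``table_order`` the coefficients are sorted by
    posterior mean within each model level (report-table convention);
    otherwise the sampler's parameter order is kept.  Quantiles are computed
    on the chains pooled after burn-in.
    """
    pooled = draws.pooled()
    if pooled.size == 0:
        raise ValidationError("no retained draws to summarize")
    if pooled.shape[0] < 1000:
        warnings.warn(
            f"only {pooled.shape[0]} pooled draws; interval estimates will be noisy",
            stacklevel=2,
        )
    q = np.quantile(pooled, [0.025, 0.25, 0.75, 0.975], axis=0)
    table = pd.DataFrame(
        {
            "covariate": [COVARIATE_LABELS.get(n, n) for n in draws.names],
            "mean": pooled.mean(axis=0),
            "sd": pooled.std(axis=0, ddof=1),
            "q2.5": q[0],
            "q25": q[1],
            "q75": q[2],
            "q97.5": q[3],
        },
        index=list(draws.names),
    )
    table["flag95"] = (table["q2.5"] > 0) | (table["q97.5"] < 0)
    table["flag50"] = (table["q25"] > 0) | (table["q75"] < 0)
    if table_order:
        order = []
        for prefix in ("alpha", "beta", "gamma"):
            block = [n for n in draws.names if n.startswith(prefix)]
            order.extend(table.loc[block].sort_values("mean").index if prefix != "alpha" else block)
        order.extend(n for n in draws.names if n.startswith("tau"))
        table = table.loc[order]
    return table
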