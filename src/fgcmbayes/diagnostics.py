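"""Convergence and model-fit diagnostics.

Gelman–Rubin: the corrected potential scale reduction factor (Rc) computed on
unsplit post-burn-in chains, with the Brooks–Gelman degrees-of-freedom
adjustment — the estimate reported by classic BUGS/JAGS workflows.  Values
below 1.1 conventionally indicate convergence.

Posterior predictive checks: for each retained draw, replicate data at both
model levels from their likelihoods and compare the mean and SD of the
replicated vectors with the observed ones.  Each Bayesian p-value is the
proportion of draws whose replicated statistic is >= the observed statistic;
values near 0 or 1 indicate misfit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import PosteriorDraws, _stacked_designs
from .preprocess import ModelInputs

__all__ = [
    "gelman_rubin",
    "convergence_report",
    "ConvergenceReport",
    "PPCReport",
    "posterior_predictive_check",
]


def gelman_rubin(chains: np.ndarray) -> float:
    """Corrected potential scale reduction factor for one parameter.

    Parameters
    ----------
    chains
        Array of shape (m, n): m >= 2 chains of n >= 10 post-burn-in draws.

    Notes
    -----
    With chain means x̄_j and variances s²_j, W = mean(s²_j) and
    B = n·var(x̄_j); the pooled estimate is σ̂² = (n−1)/n·W + B/n and
    V̂ = σ̂² + B/(m·n).  Rc = sqrt((d+3)/(d+1) · V̂/W) with d the estimated
    degrees of freedom 2V̂²/var(V̂).  Identical chains (B = 0) give Rc
    slightly below 1; chains that have not mixed give Rc well above 1.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("gelman_rubin needs >= 2 chains (shape (m, n))")
    m, n = x.shape
    if n < 10:
        raise ValidationError("gelman_rubin needs chains of length >= 10")

    xbar = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    W = s2.mean()
    B = n * xbar.var(ddof=1)
    if W == 0:
        if np.all(x == x[0, 0]):
            return 1.0
        raise ValidationError("zero within-chain variance but chains differ")

    V = (n - 1) / n * W + (1 + 1 / m) * B / n

    # Brooks–Gelman df adjustment via the sampling variance of V.
    muhat = xbar.mean()
    var_w = s2.var(ddof=1) / m
    var_b = 2 * B**2 / (m - 1)
    cov_s2_xbar2 = np.cov(s2, xbar**2, ddof=1)[0, 1]
    cov_s2_xbar = np.cov(s2, xbar, ddof=1)[0, 1]
    cov_wb = (n / m) * (cov_s2_xbar2 - 2 * muhat * cov_s2_xbar)
    var_V = (
        (n - 1) ** 2 * var_w + (1 + 1 / m) ** 2 * var_b + 2 * (n - 1) * (1 + 1 / m) * cov_wb
    ) / n**2
    if var_V <= 0:
        return float(np.sqrt(V / W))
    df = 2 * V**2 / var_V
    return float(np.sqrt((df + 3) / (df + 1) * V / W))


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-parameter Rc values against a convergence threshold."""

    table: pd.DataFrame
    threshold: float = 1.1

    @property
    def all_converged(self) -> bool:
        return bool(self.table["converged"].all())

    @property
    def max_rc(self) -> float:
        return float(self.table["rc"].max())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "threshold": self.threshold,
            "all_converged": self.all_converged,
            "rc": {p: float(r) for p, r in zip(self.table.index, self.table["rc"])},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def convergence_report(draws: PosteriorDraws, threshold: float = 1.1) -> ConvergenceReport:
    """Rc for every sampled parameter, flagged against ``threshold``."""
    rc = {name: gelman_rubin(draws.parameter(name)) for name in draws.names}
    table = pd.DataFrame({"rc": pd.Series(rc)})
    table["converged"] = table["rc"] < threshold
    return ConvergenceReport(table=table, threshold=threshold)


@dataclass(frozen=True)
class PPCReport:
    """Bayesian p-values for the mean and SD at each model level."""

    p_mean_level1: float
    p_sd_level1: float
    p_mean_level2: float
    p_sd_level2: float
    n_draws_used: int

    def values(self) -> tuple[float, float, float, float]:
        return (self.p_mean_level1, self.p_sd_level1, self.p_mean_level2, self.p_sd_level2)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def posterior_predictive_check(
    draws: PosteriorDraws,
    inputs: ModelInputs,
    seed: int = 0,
    subsample: int | None = None,
) -> PPCReport:
    """Replicate data from every retained draw and score mean/SD at each level.

    For draw (theta, tau1, tau2): ybar_rep ~ Normal(mu_i, 1/tau1) at level 1
    and y_rep ~ Normal(mu_ij, 1/tau2) at level 2.  Each p-value is
    P(T(rep) >= T(obs)) over draws, with T the mean or the sample SD.  All
    retained draws are used unless ``subsample`` evenly thins them.
    """
    pooled = draws.pooled()
    if pooled.size == 0:
        raise ValidationError("no draws for posterior predictive check")
    d = len(draws.names) - 2
    n_beta, n_gamma = inputs.X.shape[1], inputs.Z.shape[1]
    if d != 1 + n_beta + n_gamma:
        raise ValidationError(
            f"draws have {d} coefficients but inputs imply {1 + n_beta + n_gamma}"
        )
    if subsample is not None and subsample < pooled.shape[0]:
        idx = np.linspace(0, pooled.shape[0] - 1, subsample).astype(int)
        pooled = pooled[idx]

    A, B = _stacked_designs(inputs)
    theta = pooled[:, :d]
    tau1 = pooled[:, d]
    tau2 = pooled[:, d + 1]
    obs = {
        "mean1": float(np.mean(inputs.ybar)),
        "sd1": float(np.std(inputs.ybar, ddof=1)),
        "mean2": float(np.mean(inputs.y)),
        "sd2": float(np.std(inputs.y, ddof=1)),
    }

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    P = pooled.shape[0]
    stats = {k: np.empty(P) for k in ("mean1", "sd1", "mean2", "sd2")}
    # Chunked so the (draws × samples) replicate matrix never materializes
    # in full at study scale with hundreds of thousands of draws.
    chunk = max(1, int(2_000_000 // max(inputs.n_samples, 1)))
    for lo in range(0, P, chunk):
        hi = min(lo + chunk, P)
        th = theta[lo:hi]
        mu1 = th @ A.T                                   # (c, I)
        mu2 = th @ B.T                                   # (c, N)
        rep1 = mu1 + rng.standard_normal(mu1.shape) / np.sqrt(tau1[lo:hi, None])
        rep2 = mu2 + rng.standard_normal(mu2.shape) / np.sqrt(tau2[lo:hi, None])
        stats["mean1"][lo:hi] = rep1.mean(axis=1)
        stats["sd1"][lo:hi] = rep1.std(axis=1, ddof=1)
        stats["mean2"][lo:hi] = rep2.mean(axis=1)
        stats["sd2"][lo:hi] = rep2.std(axis=1, ddof=1)

    return PPCReport(
        p_mean_level1=float(np.mean(stats["mean1"] >= obs["mean1"])),
        p_sd_level1=float(np.mean(stats["sd1"] >= obs["sd1"])),
        p_mean_level2=float(np.mean(stats["mean2"] >= obs["mean2"])),
        p_sd_level2=float(np.mean(stats["sd2"] >= obs["sd2"])),
        n_draws_used=P,
    )
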