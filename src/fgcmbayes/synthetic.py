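"""Synthetic emulation of a longitudinal fecal glucocorticoid (fGCM) field study.

Generates a population of female elephants with the social covariates of the
study design (orphan status, natal/non-natal group, adult caregivers, age
mates), a bimodal seasonal vegetation (NDVI) series, and repeated dung-sample
records whose fGCM concentrations follow the two-level linear structure that
the hierarchical model in :mod:`fgcmbayes.model` fits:

    y*_ij = alpha + x_i' beta + eta_i + z_ij' gamma + eps_ij,
    eta_i ~ Normal(0, sigma1^2),   eps_ij ~ Normal(0, sigma2^2),

with x_i the standardized individual-level covariates (caregivers, age mates,
sample count, orphan, non-natal) and z_ij the standardized sample-level
covariates (age, lactating, ground time, time of day, NDVI mean, pregnancy,
NDVI SD, years without mother, optionally strongylid fecal egg count).  The
standardized response y* is mapped to ng/g dry weight through a configurable
center and scale and floored at a small positive concentration.

The generator is deterministic given the config seed: every operation derives
its own child stream from one root ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "TrueParameters",
    "simulate_individuals",
    "simulate_seasonal_covariates",
    "simulate_samples",
    "inject_outliers",
    "write_dataset",
]

#: Calendar anchor for day 0 of the study window (start of a wet season).
STUDY_START = date(2015, 4, 1)

#: Probability weights for the number of adult caregivers {0..4}, skewed low.
CAREGIVER_WEIGHTS = np.array([0.35, 0.25, 0.20, 0.12, 0.08])

#: Probability weights for the number of age mates {0..8}, decreasing.
AGE_MATE_WEIGHTS = np.arange(9, 0, -1.0) / np.arange(9, 0, -1.0).sum()

#: Fraction of samples with a missing strongylid fecal egg count.
FEC_MISSING_RATE = 0.10

# Sub-stream indices for the root SeedSequence, fixed so each operation is
# reproducible in isolation.
_STREAMS = {"individuals": 0, "seasonal": 1, "samples": 2, "outliers": 3}


def _rng(config: "SimulationConfig", stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic population and sampling."""

    n_individuals: int = 37
    n_orphans: int = 25
    n_non_natal: int = 5
    age_range_years: tuple[float, float] = (7.0, 21.0)
    samples_per_individual_mean: float = 15.0
    samples_per_individual_sd: float = 4.0
    study_length_days: int = 396  # thirteen months
    min_gap_days: int = 14
    fgcm_target_mean_ngg: float = 95.69
    fgcm_target_sd_ngg: float = 30.21
    fgcm_floor_ngg: float = 1.0
    outlier_count: int = 9
    outlier_magnitude_sd: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.n_non_natal <= self.n_orphans <= self.n_individuals):
            raise ConfigurationError(
                "require n_non_natal <= n_orphans <= n_individuals, got "
                f"{self.n_non_natal}, {self.n_orphans}, {self.n_individuals}"
            )
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        if self.min_gap_days < 1:
            raise ConfigurationError("min_gap_days must be >= 1")
        if self.study_length_days <= self.min_gap_days:
            raise ConfigurationError("study_length_days must exceed min_gap_days")
        if self.fgcm_target_sd_ngg <= 0:
            raise ConfigurationError("fgcm_target_sd_ngg must be > 0")
        if self.age_range_years[0] >= self.age_range_years[1]:
            raise ConfigurationError("age_range_years must be an increasing interval")
        if self.outlier_count < 0:
            raise ConfigurationError("outlier_count must be >= 0")


@dataclass(frozen=True)
class TrueParameters:
    """Generative coefficients on the standardized scale.

    Defaults are the study's reported posterior means: five individual-level
    coefficients (caregivers, age mates, sample count, orphan status,
    non-natal group) and eight sample-level coefficients (age, lactating,
    ground time, time of day, NDVI mean, pregnancy, NDVI SD, years without
    mother).  A ninth sample-level coefficient, for strongylid fecal egg
    counts, is optional.  sigma1/sigma2 are the individual- and sample-level
    noise SDs of the generator (not reported quantities).
    """

    alpha: float = 0.0
    beta: tuple[float, ...] = (-0.09, -0.25, -0.14, 0.06, -0.41)
    gamma: tuple[float, ...] = (-0.06, -0.10, 0.09, 0.02, -0.69, 0.08, 0.79, 0.07)
    sigma1: float = 0.3
    sigma2: float = 0.8

    def validate(self) -> None:
        if len(self.beta) != 5:
            raise ConfigurationError("beta must have exactly 5 coefficients")
        if len(self.gamma) not in (8, 9):
            raise ConfigurationError("gamma must have 8 or 9 coefficients")
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ConfigurationError("sigma1 and sigma2 must be nonnegative")


def simulate_individuals(config: SimulationConfig) -> pd.DataFrame:
    """Draw the individual table: ids, social covariates, ages, orphan history.

    Returns a frame with columns ``individual_id, f, m, o, a, age0_years,
    ybm0_years`` where ``f`` is adult caregivers (0–4), ``m`` age mates (0–8),
    ``o`` orphan status, ``a`` non-natal group membership (only orphans can be
    non-natal), ``age0_years`` the age at day 0 and ``ybm0_years`` the years
    since the mother's death at day 0 (zero for nonorphans).
    """
    config.validate()
    rng = _rng(config, "individuals")
    n = config.n_individuals

    ids = [f"ele{i + 1:03d}" for i in range(n)]
    o = np.zeros(n, dtype=int)
    o[rng.choice(n, size=config.n_orphans, replace=False)] = 1
    a = np.zeros(n, dtype=int)
    orphan_idx = np.flatnonzero(o == 1)
    if config.n_non_natal:
        a[rng.choice(orphan_idx, size=config.n_non_natal, replace=False)] = 1

    f = rng.choice(5, size=n, p=CAREGIVER_WEIGHTS)
    m = rng.choice(9, size=n, p=AGE_MATE_WEIGHTS)
    lo, hi = config.age_range_years
    age0 = rng.uniform(lo, hi, size=n)

    # Orphans lost their mother between one year ago and (age - 2) years ago,
    # capped at 12 so the covariate stays in a plausible range.
    ybm0 = np.zeros(n)
    upper = np.clip(age0[orphan_idx] - 2.0, 1.5, 12.0)
    ybm0[orphan_idx] = rng.uniform(1.0, upper)

    return pd.DataFrame(
        {
            "individual_id": ids,
            "f": f,
            "m": m,
            "o": o,
            "a": a,
            "age0_years": age0,
            "ybm0_years": ybm0,
        }
    )


def _seasonal_curve(days: np.ndarray) -> np.ndarray:
    """Noise-free bimodal greenness curve: two wet-season peaks per year."""
    doy = (days + (STUDY_START - date(STUDY_START.year, 1, 1)).days) % 365.25
    return 0.42 + 0.13 * np.sin(4.0 * np.pi * (doy - 89.3) / 365.25)


def simulate_seasonal_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Daily NDVI spatial mean and SD over the study window.

    The mean follows a smooth two-peaks-per-year greenness curve with small
    observation noise; the spatial SD is elevated during seasonal transitions,
    proportional to the absolute rate of change of the smooth curve (patchy
    green-up/brown-down), plus noise.  Both series are strictly positive.
    """
    config.validate()
    if config.study_length_days < 30:
        raise ConfigurationError("study_length_days must be >= 30 for a seasonal series")
    rng = _rng(config, "seasonal")
    days = np.arange(config.study_length_days)
    curve = _seasonal_curve(days)
    ndvi_mean = curve + rng.normal(0.0, 0.004, size=days.size)
    rate = np.abs(np.gradient(curve))
    ndvi_sd = 0.035 + 12.0 * rate + rng.normal(0.0, 0.003, size=days.size)
    return pd.DataFrame(
        {
            "day": days,
            "ndvi_mean": np.clip(ndvi_mean, 0.01, None),
            "ndvi_sd": np.clip(ndvi_sd, 0.005, None),
        }
    )


def _episode_series(rng: np.random.Generator, length: int, p_on: float, mean_len: float) -> np.ndarray:
    """Piecewise-constant 0/1 process: persistent multi-month episodes."""
    out = np.empty(length, dtype=int)
    t = 0
    while t < length:
        dur = max(30, int(rng.exponential(mean_len)))
        out[t : t + dur] = int(rng.random() < p_on)
        t += dur
    return out


def _sample_days(rng: np.random.Generator, n_samples: int, length: int, gap: int) -> np.ndarray:
    """``n_samples`` sorted days in [0, length) with consecutive gaps >= gap."""
    slack = (length - 1) - (n_samples - 1) * gap
    base = np.sort(rng.choice(slack + 1, size=n_samples, replace=True))
    return base + gap * np.arange(n_samples)


def _std0(x: np.ndarray) -> np.ndarray:
    """Standardize, mapping a constant column to zeros (its coefficient then
    contributes nothing, which is the natural degenerate limit)."""
    s = np.std(x, ddof=1) if x.size > 1 else 0.0
    if s == 0:
        return np.zeros_like(x, dtype=float)
    return (x - np.mean(x)) / s


def simulate_samples(
    individuals: pd.DataFrame,
    seasonal: pd.DataFrame,
    params: TrueParameters,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Generate the long-format sample table with fGCM responses.

    Per individual, a sample count near the configured mean (floor 2) is drawn
    and sampling days are placed at least ``min_gap_days`` apart.  Time-varying
    covariates advance with the sampling date; the standardized response is
    built from the two-level linear structure and mapped to ng/g.  The realized
    SD of the standardized response is attached as ``frame.attrs["response_scale"]``
    (the factor linking generator-scale coefficients to coefficients fitted
    after re-standardization of the response).
    """
    config.validate()
    params.validate()
    if individuals.empty:
        raise ConfigurationError("individuals table is empty")
    if len(seasonal) < config.study_length_days:
        raise ConfigurationError(
            f"seasonal series covers {len(seasonal)} days < study_length_days={config.study_length_days}"
        )
    rng = _rng(config, "samples")
    length, gap = config.study_length_days, config.min_gap_days
    max_samples = (length - 1) // gap + 1

    ndvi_mean = seasonal["ndvi_mean"].to_numpy()
    ndvi_sd = seasonal["ndvi_sd"].to_numpy()

    rows: list[dict] = []
    counts: dict[str, int] = {}
    for ind in individuals.itertuples(index=False):
        n_s = int(round(rng.normal(config.samples_per_individual_mean, config.samples_per_individual_sd)))
        n_s = int(np.clip(n_s, 2, max_samples))
        counts[ind.individual_id] = n_s
        days = _sample_days(rng, n_s, length, gap)
        preg = _episode_series(rng, length, 0.30, 150.0)
        lact = _episode_series(rng, length, 0.45, 180.0)
        for k, d in enumerate(days):
            w = np.nan if rng.random() < FEC_MISSING_RATE else rng.gamma(2.0, 400.0)
            rows.append(
                {
                    "individual_id": ind.individual_id,
                    "sample_id": f"{ind.individual_id}-s{k + 1:02d}",
                    "date": (STUDY_START + timedelta(days=int(d))).isoformat(),
                    "day": int(d),
                    "g": ind.age0_years + d / 365.25,
                    "l": int(lact[d]),
                    "p": int(preg[d]),
                    "t": rng.uniform(0.25, 0.75),
                    "s": rng.exponential(1.0),
                    "v": ndvi_mean[d],
                    "z": ndvi_sd[d],
                    "b": (ind.ybm0_years + d / 365.25) if ind.o == 1 else 0.0,
                    "w": w,
                }
            )
    samples = pd.DataFrame(rows)

    # Individual-level linear predictor on generator-standardized covariates.
    ind = individuals.set_index("individual_id")
    n_col = ind.index.map(counts).to_numpy(dtype=float)
    x_cols = [
        _std0(ind["f"].to_numpy(dtype=float)),
        _std0(ind["m"].to_numpy(dtype=float)),
        _std0(n_col),
        _std0(ind["o"].to_numpy(dtype=float)),
        _std0(ind["a"].to_numpy(dtype=float)),
    ]
    lin1 = sum(b * col for b, col in zip(params.beta, x_cols))
    eta = rng.normal(0.0, params.sigma1, size=len(ind)) if params.sigma1 > 0 else np.zeros(len(ind))
    per_ind = pd.Series(lin1 + eta, index=ind.index)

    z_cols = [
        _std0(samples["g"].to_numpy()),
        _std0(samples["l"].to_numpy(dtype=float)),
        _std0(samples["s"].to_numpy()),
        _std0(samples["t"].to_numpy()),
        _std0(samples["v"].to_numpy()),
        _std0(samples["p"].to_numpy(dtype=float)),
        _std0(samples["z"].to_numpy()),
        _std0(samples["b"].to_numpy()),
    ]
    if len(params.gamma) == 9:
        wvals = samples["w"].to_numpy()
        wstd = np.where(np.isnan(wvals), np.nanmean(wvals), wvals)
        z_cols.append(_std0(wstd))
    lin2 = sum(g * col for g, col in zip(params.gamma, z_cols))
    eps = rng.normal(0.0, params.sigma2, size=len(samples)) if params.sigma2 > 0 else np.zeros(len(samples))

    y_star = params.alpha + per_ind.loc[samples["individual_id"]].to_numpy() + lin2 + eps
    # The latent response has SD sqrt(var(lin) + sigma1^2 + sigma2^2) > 1; it is
    # normalized by its realized SD before the ng/g mapping so the configured
    # target center and scale are what the output table actually shows.  That
    # realized SD is the factor linking generator-scale coefficients to
    # coefficients fitted after the pipeline re-standardizes the response.
    scale = float(np.std(y_star, ddof=1)) if len(y_star) > 1 and np.std(y_star, ddof=1) > 0 else 1.0
    samples["y_ngg"] = np.maximum(
        config.fgcm_floor_ngg,
        config.fgcm_target_mean_ngg + config.fgcm_target_sd_ngg * (y_star - np.mean(y_star)) / scale,
    )
    samples["is_outlier"] = False

    cols = [
        "individual_id", "sample_id", "date", "day", "y_ngg",
        "g", "l", "p", "t", "s", "v", "z", "b", "w", "is_outlier",
    ]
    samples = samples[cols]
    samples.attrs["response_scale"] = scale
    return samples


def inject_outliers(samples: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Displace one sample in each of ``outlier_count`` distinct individuals.

    The individuals with the most samples are chosen (ties broken by id) so
    the planted points are discardable by a within-individual 3-SD rule, which
    needs enough samples to be able to flag anything.  Each chosen sample is
    shifted upward by ``outlier_magnitude_sd`` times that individual's sample
    SD and flagged in the ``is_outlier`` provenance column.
    """
    config.validate()
    if config.outlier_count == 0:
        return samples.copy()
    counts = samples["individual_id"].value_counts()
    if config.outlier_count > len(counts):
        raise ConfigurationError(
            f"outlier_count={config.outlier_count} exceeds {len(counts)} distinct individuals"
        )
    order = sorted(counts.index, key=lambda i: (-counts[i], i))
    targets = order[: config.outlier_count]

    rng = _rng(config, "outliers")
    out = samples.copy()
    scale = samples.attrs.get("response_scale")
    for ind_id in targets:
        idx = out.index[out["individual_id"] == ind_id]
        sd = out.loc[idx, "y_ngg"].std(ddof=1)
        victim = rng.choice(idx)
        out.loc[victim, "y_ngg"] += config.outlier_magnitude_sd * sd
        out.loc[victim, "is_outlier"] = True
    if scale is not None:
        out.attrs["response_scale"] = scale
    return out


def write_dataset(
    outdir: str | Path,
    config: SimulationConfig,
    params: TrueParameters | None = None,
) -> dict[str, Path]:
    """Generate a full synthetic study and write CSV tables plus a truth sidecar.

    Writes ``individuals.csv``, ``samples.csv`` (with planted outliers),
    ``seasonal.csv`` and ``truth.json`` (true parameters, seed, and the
    response scale linking generator coefficients to re-standardized fits).
    """
    params = params or TrueParameters()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    individuals = simulate_individuals(config)
    seasonal = simulate_seasonal_covariates(config)
    samples = simulate_samples(individuals, seasonal, params, config)
    samples = inject_outliers(samples, config)

    paths = {
        "individuals": outdir / "individuals.csv",
        "samples": outdir / "samples.csv",
        "seasonal": outdir / "seasonal.csv",
        "truth": outdir / "truth.json",
    }
    individuals[["individual_id", "f", "m", "o", "a"]].to_csv(paths["individuals"], index=False)
    samples.to_csv(paths["samples"], index=False)
    seasonal.to_csv(paths["seasonal"], index=False)
    truth = {
        "params": dataclasses.asdict(params),
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "response_scale": samples.attrs["response_scale"],
    }
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths
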