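"""Shared fixtures: small synthetic studies and fitted posteriors."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fgcmbayes as fb

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> fb.SimulationConfig:
    return fb.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def study_tables(default_config):
    """Default-scale synthetic study: individuals, seasonal series, samples
    with planted outliers (the deposit emulation)."""
    individuals = fb.simulate_individuals(default_config)
    seasonal = fb.simulate_seasonal_covariates(default_config)
    samples = fb.simulate_samples(individuals, seasonal, fb.TrueParameters(), default_config)
    samples = fb.inject_outliers(samples, default_config)
    return individuals, seasonal, samples


@pytest.fixture(scope="session")
def study_inputs(study_tables):
    individuals, _, samples = study_tables
    kept, _ = fb.remove_outliers(samples)
    return fb.build_design(kept, individuals[["individual_id", "f", "m", "o", "a"]])


@pytest.fixture(scope="session")
def study_fit(study_inputs):
    """A short but well-mixed fit of the study-scale emulation."""
    mcmc = fb.MCMCConfig(n_chains=3, n_iterations=4000, n_burnin=500, seed=5)
    return fb.fit(study_inputs, mcmc=mcmc)


def make_small_inputs(seed: int = 0, I: int = 6, N: int = 30, n_beta: int = 1, n_gamma: int = 1):
    """Hand-built standardized ModelInputs for oracle tests (not via build_design)."""
    rng = np.random.default_rng(seed)

    def std(x):
        return (x - x.mean()) / x.std(ddof=1)

    X = np.column_stack([std(rng.normal(size=I)) for _ in range(n_beta)]) if n_beta else np.empty((I, 0))
    Z = np.column_stack([std(rng.normal(size=N)) for _ in range(n_gamma)]) if n_gamma else np.empty((N, 0))
    sample_index = np.sort(rng.integers(0, I, size=N))
    # make sure every individual has at least one sample
    sample_index[:I] = np.arange(I)
    sample_index = np.sort(sample_index)
    y = std(rng.normal(size=N))
    ybar = np.bincount(sample_index, weights=y, minlength=I) / np.bincount(sample_index, minlength=I)
    return fb.ModelInputs(
        individual_index=tuple(f"i{k}" for k in range(I)),
        X=X,
        ybar=ybar,
        sample_index=sample_index,
        Z=Z,
        y=y,
        standardization=fb.StandardizationParams(means={}, sds={}),
        level1_names=tuple(f"x{k}" for k in range(n_beta)),
        level2_names=tuple(f"z{k}" for k in range(n_gamma)),
    )
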