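"""Shared fixtures.

The "benchmark" fixtures reproduce the package's reference synthetic
scenario (T=400 years, true temperature effect 1.5, latent AR(1) with
rho=0.8, sigma=0.3) and one converged temperature-model fit on it; both
are expensive, so they are session-scoped and shared across test modules.
"""

import numpy as np
import pytest

from countflux import (
    McmcConfig,
    ModelSpec,
    PriorSpec,
    SyntheticConfig,
    generate_dataset,
    run_mcmc,
)

BENCHMARK_SEED = 1
BENCHMARK_FIT_SEED = 11


@pytest.fixture(scope="session")
def benchmark_data():
    dataset, truth = generate_dataset(SyntheticConfig(seed=BENCHMARK_SEED))
    return dataset, truth


@pytest.fixture(scope="session")
def benchmark_fit(benchmark_data):
    """Temperature-model fit of the benchmark at the default test budget."""
    dataset, _ = benchmark_data
    config = McmcConfig(n_iterations=100_000, burn_in=1_000, seed=BENCHMARK_FIT_SEED)
    return run_mcmc(
        dataset,
        ModelSpec.from_preset("temperature"),
        PriorSpec(),
        config,
    )


@pytest.fixture()
def small_data():
    dataset, truth = generate_dataset(SyntheticConfig(n_years=80, seed=4))
    return dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
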