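import numpy as np
import pytest

import kernelvar as kv


@pytest.fixture(scope="session")
def grid() -> kv.TimeGrid:
    return kv.DEFAULT_GRID


@pytest.fixture(scope="session")
def kernels(grid) -> kv.GroundTruthKernels:
    return kv.default_kernels(grid)


@pytest.fixture(scope="session")
def clean_animal(grid, kernels):
    """A noiseless, unit-gain animal whose events avoid the baseline window
    (so the sequential fit is exactly identified)."""
    spec = kv.AnimalSpec("clean", n_trials=1200, sigma_gain=0.0, sigma_noise=0.0,
                         event_rate_params={"t_min": -0.5})
    return spec, kv.synth.generate_animal(spec, kernels, grid, rng_seed=42)


@pytest.fixture(scope="session")
def clean_sequential_fit(grid, clean_animal):
    _, trials = clean_animal
    sel = kv.select_trials(trials, grid, isolation_window=2.5)
    return sel, kv.sequential_fit(trials, sel, grid, regularizer="ols")


@pytest.fixture(scope="session")
def noisy_animal(grid, kernels):
    """A realistic animal: multiplicative gain variability plus sensor noise."""
    spec = kv.AnimalSpec("noisy", n_trials=1200, sigma_gain=0.25, sigma_noise=0.03)
    return spec, kv.synth.generate_animal(spec, kernels, grid, rng_seed=7)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
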