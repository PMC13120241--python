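import numpy as np
import pytest

from enofuse.synthetic import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def fast_config() -> SimConfig:
    """Small campaign reused by read-only tests."""
    return SimConfig(n_samples_per_class=15, n_days=10, seed=123)


@pytest.fixture(scope="session")
def fast_dataset(fast_config):
    return simulate_dataset(fast_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def clean_trace_config() -> SimConfig:
    """Noise-free, undistorted, drift-free configuration for exact checks."""
    return SimConfig(
        noise_sd_v=0.0,
        drift_rate=0.0,
        day_effect_sd=0.0,
        distort_with_surface=False,
        seed=7,
    )
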