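import numpy as np
import pytest

from breathct import SimConfig, simulate_study

STUDY_SEED = 1  # canonical study seed used across the suite


@pytest.fixture(scope="session")
def study():
    """Default 3-device linked study (86 samples, 41 meal / 45 no-meal each)."""
    return simulate_study(SimConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def identity_study():
    """Same study measured by three identical, noise-free instruments."""
    k = 18
    cfg = SimConfig(
        seed=STUDY_SEED,
        device_gain=[np.eye(k)] * 3,
        device_offset=[np.zeros(k)] * 3,
        standard_noise_sd=0.0,
    )
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
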