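import numpy as np
import pytest

from movefuse import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def clean_cfg():
    """Zero-corruption conditions: every trial equals its class template."""
    return SyntheticConfig(
        n_classes=4, n_sensors=2, axes_per_sensor=3, base_duration=32,
        duration_jitter=0.0, warp_intensity=0.0, shift_max=0, noise_sigma=0.0,
        trials_per_class=4, seed=11,
    )


@pytest.fixture(scope="session")
def clean_data(clean_cfg):
    return generate_dataset(clean_cfg)


@pytest.fixture(scope="session")
def noisy_cfg():
    """Small corrupted ensemble for classifier plumbing tests."""
    return SyntheticConfig(
        n_classes=3, n_sensors=2, axes_per_sensor=2, base_duration=32,
        trials_per_class=6, seed=7,
    )


@pytest.fixture(scope="session")
def noisy_data(noisy_cfg):
    return generate_dataset(noisy_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
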