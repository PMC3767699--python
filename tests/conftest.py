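import numpy as np
import pytest

from netrel.synthetic import GeneratorConfig, NoiseSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """A small but otherwise faithful study layout for fast tests."""
    return GeneratorConfig(n_subjects=4, n_channels=10, fs=25.0,
                           duration=120.0, icc_target=0.7, seed=123)


@pytest.fixture
def quiet_config():
    """No confounds or instrument noise: data equal the latent sources."""
    return GeneratorConfig(
        n_subjects=2, n_channels=8, fs=25.0, duration=240.0, icc_target=1.0,
        noise_spec=NoiseSpec(cardiac_amp=0.0, respiratory_amp=0.0,
                             mayer_amp=0.0, instrument_sigma=0.0),
        seed=7)
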