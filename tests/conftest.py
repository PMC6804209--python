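import numpy as np
import pytest

from ramanpipe import synth
from ramanpipe.spectra import RamanSpectrum


@pytest.fixture(scope="session")
def fast_config():
    """Small, cheap generator config shared across tests."""
    return synth.SyntheticConfig(n_spectra_per_class=10, noise_sd=0.02, seed=123)


@pytest.fixture(scope="session")
def gland_profile():
    return synth.make_class_profile("gland", rng_seed=7)


@pytest.fixture(scope="session")
def small_dataset(fast_config):
    return synth.simulate_labeled_dataset(fast_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def ramp_spectrum():
    wn = np.linspace(500.0, 3200.0, 500)
    return RamanSpectrum(wn, np.linspace(1.0, 2.0, 500))
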