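import numpy as np
import pytest

import usdeblur as u


@pytest.fixture
def cfg():
    """Default simulation conditions: 512 samples, 20 MHz, 3.2 MHz 3-period pulse."""
    return u.SimConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def psf_env(cfg):
    """Unit-peak envelope of the default simulated pulse."""
    return u.normalize_psf_envelope(u.gen_rf_psf(cfg))
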