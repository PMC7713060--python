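import numpy as np
import pytest

from svfcs import ObservationVolume


@pytest.fixture
def vol():
    """Calibrated default volume: w0 = 310 nm, z0/w0 = 5, gamma = 0.35."""
    return ObservationVolume.default()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
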