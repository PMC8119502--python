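import numpy as np
import pytest
from scipy.ndimage import gaussian_filter


def make_speckle(shape=(256, 256), feature_sigma=1.0, seed=0):
    """Band-limited speckle with ~3 px features, mean 1000, std 300."""
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.standard_normal(shape), feature_sigma, mode="wrap")
    return 1000.0 + 300.0 * img / img.std()


@pytest.fixture
def speckle():
    return make_speckle()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
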