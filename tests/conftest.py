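import numpy as np
import pytest

from sddseg import GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_band_image():
    """Flat dark square (level 60) on a flat bright field (level 200)."""
    px = np.full((64, 64), 200, dtype=np.int64)
    px[20:40, 20:40] = 60
    return GrayImage(px)


@pytest.fixture
def noisy_constant_image(rng):
    """Constant level 128 plus i.i.d. Gaussian noise, sigma = 10 levels."""
    px = np.clip(np.rint(128 + rng.normal(0, 10, (96, 96))), 0, 255).astype(np.int64)
    return GrayImage(px)


def make_image(arr, bitdepth=8):
    return GrayImage(np.asarray(arr, dtype=np.int64), bitdepth=bitdepth)
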