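import numpy as np
import pytest

from irismooth.preprocess import GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def gradient_image():
    """A 64x64 ramp covering the full gray range."""
    px = np.tile(np.linspace(0, 255, 64), (64, 1))
    return GrayImage(px)


@pytest.fixture
def bimodal_image(rng):
    """Two well-separated intensity populations, 10^4 pixels each."""
    lo = rng.normal(60, 10, 10_000)
    hi = rng.normal(180, 10, 10_000)
    px = np.clip(np.concatenate([lo, hi]), 0, 255).reshape(200, 100)
    return GrayImage(px)
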