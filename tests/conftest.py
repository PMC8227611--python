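import numpy as np
import pytest

from lenscat.io_formats import GreyImage
from lenscat.synthetic import SyntheticLensConfig

#: Resolution-scaled Gaussian bandwidth for the 480x270 frames used in tests.
QUARTER_SIGMA = 1.25


@pytest.fixture
def quarter_cfg():
    """Factory for phantom configs on a 480x270 frame."""

    def make(**kwargs):
        defaults = dict(width=480, height=270)
        defaults.update(kwargs)
        return SyntheticLensConfig(**defaults)

    return make


@pytest.fixture
def flat_image():
    """Factory for constant-valued grey images."""

    def make(value=7, shape=(16, 16)):
        return GreyImage(pixels=np.full(shape, value, dtype=np.uint8))

    return make
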