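import numpy as np
import pytest

from calciscope import BinaryMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_mask(rng):
    """A 48x48 Bernoulli(0.3) mask with nonzero variance."""
    return BinaryMask((rng.random((48, 48)) < 0.3).astype(np.uint8), pixels_per_micron=2.73)


def centered_disk_mask(size: int, radius: int, ppm: float = 2.73) -> BinaryMask:
    yy, xx = np.mgrid[0:size, 0:size]
    c = size // 2
    return BinaryMask(
        ((yy - c) ** 2 + (xx - c) ** 2 <= radius * radius).astype(np.uint8), ppm
    )
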