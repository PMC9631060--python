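import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def disk_mask(size: int, radius: float, center=None) -> np.ndarray:
    """Filled boolean disk (pixel centers within radius)."""
    c = (size - 1) / 2.0 if center is None else center
    cy, cx = (c, c) if np.isscalar(c) else c
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
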