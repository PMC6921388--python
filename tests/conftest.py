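import numpy as np
import pytest

import zdiskseg as z


@pytest.fixture
def config():
    return z.sbfsem_preset()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bar_slice():
    """Pre-processed-style slice with one smoothed 2-px bright vertical bar."""
    img = np.full((40, 60), 107.0)
    img[:, 30:32] = 255.0
    return z.gaussian_smooth(img, 1.2), (30, 32)
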