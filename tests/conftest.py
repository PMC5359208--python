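import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_images(rng):
    """Small random integer images for oracle-equivalence checks."""
    return [rng.integers(0, 16, size=(rng.integers(4, 13), rng.integers(4, 13)))
            .astype(np.uint8) for _ in range(30)]
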