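import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_8bit_images():
    """Small random integer images for oracle-equivalence checks."""
    rng = np.random.default_rng(1234)
    return [
        rng.integers(0, 256, size=(16, 16)).astype(float) for _ in range(50)
    ]
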