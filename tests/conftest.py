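import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(20220919)


@pytest.fixture
def random_block(rng):
    """A random 3^3 block of bins 1..10 (already quantised)."""
    return rng.integers(1, 11, size=(3, 3, 3))
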