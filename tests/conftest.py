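import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from netfreq import Sample


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def normal_sample(rng):
    """100 draws from N(100, 20) — the canonical walkthrough shape."""
    return Sample(rng.normal(100, 20, size=100), label="normal n=100")


@pytest.fixture
def lognormal_sample(rng):
    return Sample(rng.lognormal(1, 0.5, size=200), label="lognormal n=200")
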