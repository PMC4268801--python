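import numpy as np
import pytest

from glycosim import GlycationParams


@pytest.fixture
def params():
    """Population-mean kinetics: k = 1.296e-9 l/(mmol s), 120-day life span."""
    return GlycationParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
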