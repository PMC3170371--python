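import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    """Seeded generator shared by stochastic tests."""
    return np.random.default_rng(20110909)


@pytest.fixture
def uniform_10k(rng):
    """A large complete-null family (10,000 Uniform(0,1) p-values)."""
    return rng.random(10_000)
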