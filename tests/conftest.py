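import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def decay_surrogate():
    """Order-5 Hermite surrogate of A(1) = exp(-k), k ~ Lognormal(0.5, 0.2)."""
    from specex import fit
    from specex.models import DECAY_SPEC

    return fit(lambda k: np.exp(-k[0]), [DECAY_SPEC], 5)
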