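import numpy as np
import pytest

from cobrairs.densitometry import EffectiveLengthTable


@pytest.fixture(scope="session")
def as_printed():
    return EffectiveLengthTable.as_printed()


@pytest.fixture(scope="session")
def geometric():
    return EffectiveLengthTable.geometric()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_simplex_pct(rng, n=1):
    """Random frequency vectors on the 100-simplex."""
    return rng.dirichlet(np.ones(4), size=n) * 100.0
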