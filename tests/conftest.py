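import numpy as np
import pytest

from omihet.simulate import generate_irf


@pytest.fixture(scope="session")
def irf():
    """Default instrument response function on the standard 256-bin grid."""
    return generate_irf(0.25, 256, 0.039)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
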