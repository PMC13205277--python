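import numpy as np
import pytest

from transrr.losses import pseudo_huber, quadratic, smoothed_huber


@pytest.fixture(scope="session")
def sh_loss():
    """Default smoothed Huber loss (delta 1.35, eta 0.1)."""
    return smoothed_huber()


@pytest.fixture(scope="session")
def ph_loss():
    return pseudo_huber()


@pytest.fixture(scope="session")
def quad_loss():
    return quadratic()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
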