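import numpy as np
import pytest

import wextropy as wx


@pytest.fixture(scope="session")
def exp1():
    return wx.exponential(1.0)


@pytest.fixture(scope="session")
def unif():
    return wx.uniform01()


@pytest.fixture(scope="session")
def p2x():
    return wx.power2x()


@pytest.fixture(scope="session")
def ray():
    return wx.rayleigh1()


@pytest.fixture(scope="session")
def logn():
    return wx.lognormal(0.0, 1.0)


@pytest.fixture(scope="session")
def exp_sample50():
    """A fixed n=50 standard-exponential sample used by the oracle checks."""
    rng = np.random.default_rng(123)
    return wx.LifetimeSample(rng.exponential(size=50))


@pytest.fixture(scope="session")
def all_distributions(exp1, unif, p2x, ray, logn):
    return [exp1, unif, p2x, ray, logn]
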