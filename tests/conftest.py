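import pytest

from stochemostat import preset


@pytest.fixture(scope="session")
def ergodic_low():
    """Weak-noise ergodic regime: Q=1, sigma1=0.05, sigma2=0.1."""
    return preset("stationary-low-noise")


@pytest.fixture(scope="session")
def ergodic_moderate():
    return preset("stationary-moderate-noise")


@pytest.fixture(scope="session")
def washout():
    """High dilution: Q=2.2, extinction case (i)."""
    return preset("washout-high-dilution")


@pytest.fixture(scope="session")
def haldane_extinction():
    """Q=1.6: extinction through the Haldane discriminant (case ii)."""
    return preset("extinction-moderate-dilution")


@pytest.fixture(scope="session")
def noise_extinction():
    """Q=1.1, sigma2=1.5: noise-induced extinction."""
    return preset("noise-induced-extinction")


@pytest.fixture(scope="session")
def bistable():
    return preset("bistable")
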