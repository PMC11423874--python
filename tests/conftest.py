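import numpy as np
import pytest

from flimmet import DecayParams, TimeAxis


@pytest.fixture(scope="session")
def axis() -> TimeAxis:
    """Default 80 MHz / 256-bin TCSPC time axis."""
    return TimeAxis()


@pytest.fixture(scope="session")
def reference_params() -> DecayParams:
    """A typical NAD(P)H decay: 30% bound fraction, tau_avg = 1.19 ns."""
    return DecayParams(alpha1=0.7, tau1=0.5, alpha2=0.3, tau2=2.8)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
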