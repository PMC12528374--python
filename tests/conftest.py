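import numpy as np
import pytest

from viscoclutch.engine import ClutchParams, MotorParams, SimConfig
from viscoclutch.substrate import SLSParams


@pytest.fixture
def sls_unit():
    """k1 = k2 = eta = 1: tau = 1 s, instantaneous 2, equilibrium 1."""
    return SLSParams(k1=1.0, k2=1.0, eta=1.0)


@pytest.fixture
def slip_clutch():
    """Classic slip-bond clutch with unit rates, for closed-form checks."""
    return ClutchParams(
        k_on=1.0, k_off0=1.0, f_bond=2.0, f_unfold=10.0, k_vin=1.0,
        d_recruit=5, bond_law="slip",
    )


@pytest.fixture
def motors():
    return MotorParams()


@pytest.fixture
def quick_sim():
    """Short run for smoke-level engine tests."""
    return SimConfig(duration=10.0, record_dt=0.05, seed=1234)


@pytest.fixture
def rng():
    return np.random.default_rng(77)
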