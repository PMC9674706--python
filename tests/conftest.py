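import numpy as np
import pytest

from preqsense import ReceptorKinetics


@pytest.fixture
def insulin_kin() -> ReceptorKinetics:
    """A 'good antibody' insulin receptor: K_D = 500 pM, k_on = 1e6 /(M s)."""
    return ReceptorKinetics(k_on=1e6, k_off=5e-4)


@pytest.fixture
def mab1_kin() -> ReceptorKinetics:
    """Anti-TNFa monoclonal antibody constants used by the sensorgram fixtures."""
    return ReceptorKinetics(k_on=3.80e5, k_off=2.5e-3)


@pytest.fixture
def unit_kin() -> ReceptorKinetics:
    """Nondimensional kinetics (k_on = k_off = 1) for scale-free property checks."""
    return ReceptorKinetics(k_on=1.0, k_off=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
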