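import numpy as np
import pytest

from oligokin.params import Condition, Protocol, RateParameters, ScreeningGeometry


@pytest.fixture(scope="session")
def igg1():
    return RateParameters()


@pytest.fixture(scope="session")
def geometry():
    return ScreeningGeometry()


@pytest.fixture
def reference_condition():
    """33 nM IgG1 on the 5% DNP surface, 3 min incubation."""
    return Condition(variant="IgG1", c_bulk=33e-9, dnp_fraction=0.05, t_incubation=180.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def quick_protocol():
    """Short observation window for tests that only need protocol mechanics."""
    return Protocol(t_wash=60.0, t_observe=300.0)
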