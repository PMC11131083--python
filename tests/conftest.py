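import numpy as np
import pytest

from gelpore import GelParams, make_problem

P0 = 101325.0


@pytest.fixture
def gel() -> GelParams:
    return GelParams()


@pytest.fixture
def default_problem():
    """Reference core/shell setup: stiff skin, strong drying."""
    return make_problem(G_ratio=20.0, Pi_ext_over_G=20.0)


@pytest.fixture
def free_swelling_problem():
    """No external osmotic pressure: the initial state is an equilibrium."""
    return make_problem(Pi_ext_over_G=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240516)
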