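import numpy as np
import pytest

from thymopt import ControlProblem, CostParams, EncounterModel


@pytest.fixture
def deg_model():
    return EncounterModel.degenerate(0.275, 1000)


@pytest.fixture
def gamma_exp_model():
    """Exponentially distributed rates (Gamma a=1) with mean 0.1."""
    return EncounterModel.gamma(shape=1.0, rate_param=10.0, n=1000)


@pytest.fixture
def qs_cost():
    """K·u·n/m = 1e4 with n = 1000."""
    return CostParams(K=10.0, m=1.0, u=1.0)


@pytest.fixture
def three_phase_problem(deg_model):
    """Three-phase demonstration parameters with u pinned to 1."""
    return ControlProblem(
        cost=CostParams(K=0.001, m=1.0, u=1.0), model=deg_model, T=10.0, h_max=3.0
    )


@pytest.fixture
def two_phase_problem():
    """Two-phase demonstration parameters (tight production cap), u = 1."""
    return ControlProblem(
        cost=CostParams(K=0.001, m=1.0, u=1.0),
        model=EncounterModel.degenerate(0.2751, 1000),
        T=10.0,
        h_max=0.1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
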