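import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fluxcanal import ModelParams, ResponseFunction, State, TissueGraph, make_grid

settings.register_profile(
    "package", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("package")


@pytest.fixture
def two_cell():
    return TissueGraph(2, [(0, 1)])


@pytest.fixture
def grid3():
    return make_grid(3, 3)


@pytest.fixture
def quad():
    return ResponseFunction.quadratic()


@pytest.fixture
def blowup_setup(two_cell):
    """Two-cell slow-limit configuration with a strong PIN-cycling gain:
    quadratic response diverges in finite time, a bounded response does not."""
    params = ModelParams(alpha_a=1.0, beta_a=1.0, mu=1.0, lam=1.0,
                         alpha_p=50.0, beta_p=1.0)
    init = State(np.array([2.0, 1.0]), np.array([1.0, 0.0]))
    return two_cell, params, init
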