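import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from grextrap import (
    BoundKernel,
    Matern,
    MonomialBound,
    SimulationLog,
    central_difference_problem,
    trapezoid_problem,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def cd_testbed():
    return central_difference_problem(s=2)


@pytest.fixture(scope="session")
def tz_testbed():
    return trapezoid_problem()


@pytest.fixture
def matern2_bk():
    return BoundKernel(MonomialBound(2), Matern(2))


@pytest.fixture
def simple_log(cd_testbed):
    X = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
    y = np.array([cd_testbed.evaluator(x) for x in X])
    return SimulationLog(X.reshape(-1, 1), y)
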