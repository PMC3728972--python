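import warnings

import numpy as np
import pytest

from declinewatch.params import LifeHistoryParams, PressureScenario

warnings.filterwarnings("ignore", message="Covariance of the parameters")


@pytest.fixture(scope="session")
def medium():
    return LifeHistoryParams.preset("medium")


@pytest.fixture(scope="session")
def p1_low():
    return PressureScenario("P1", "low")


@pytest.fixture(scope="session")
def f3_low():
    return PressureScenario("F3", "low")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
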