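import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mbpredict.encoding import EncodingParams
from mbpredict.plasticity import pack_battery, paper_fit
from mbpredict.protocols import enumerate_experiment_battery

settings.register_profile(
    "suite", max_examples=25, derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def enc_paper() -> EncodingParams:
    """Published Weber-Fechner encoding of the predictive-rule fit."""
    return EncodingParams(S0=6.90, alpha=0.79, tau_o=14.25)


@pytest.fixture(scope="session")
def predictive_paper():
    """Published predictive-rule parameter set (adaptive learning rate)."""
    return paper_fit("predictive")


@pytest.fixture(scope="session")
def battery_coarse():
    """The 28-condition battery on the fitting grid (dt = 0.05 s)."""
    return enumerate_experiment_battery(0.05)


@pytest.fixture(scope="session")
def packed_battery(battery_coarse):
    return pack_battery(battery_coarse)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
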