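import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from selstop.synthetic import default_params, simulate_study  # noqa: E402
from selstop.task_model import TaskCondition  # noqa: E402


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def mix_study(params):
    """One 9-participant mix-condition cohort (600-trial sessions)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_study(9, params, seed=20240, conditions=(TaskCondition.MIX,),
                              mix_trials=600)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
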