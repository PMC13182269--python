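import logging

import numpy as np
import pytest

from dynrisk.datasets import ScenarioConfig
from dynrisk.joint import JointModelSpec, fit_joint_model
from dynrisk.simulate import simulate_cohort, simulate_dataset, simulate_joint_law

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def small_config():
    return ScenarioConfig(n_per_group=20, slope_coef=0.1, resid_sd=0.5)


@pytest.fixture(scope="session")
def small_scenario_data(small_config):
    return simulate_dataset(small_config, seed=1)


@pytest.fixture(scope="session")
def joint_theta():
    return {
        "beta": np.array([6.0, 0.1]),
        "D": np.array([[0.25, 0.01], [0.01, 0.04]]),
        "sigma2": 0.09,
        "log_kappa": np.log(1.5),
        "log_lambda": np.log(0.005),
        "alpha": 0.8,
    }


@pytest.fixture(scope="session")
def joint_law_data(joint_theta):
    return simulate_joint_law(joint_theta, 120, np.linspace(0, 15, 6), 20.0, seed=7)


@pytest.fixture(scope="session")
def jm_fit_small(small_scenario_data):
    return fit_joint_model(small_scenario_data)


@pytest.fixture(scope="session")
def fast_spec():
    return JointModelSpec(n_gh=7, n_gl=10)


@pytest.fixture(scope="session")
def cohort_small():
    return simulate_cohort(
        n_cases=8, n_controls=8, n_features=10, n_assoc=2, seed=3
    )
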