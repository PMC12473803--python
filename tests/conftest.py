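import numpy as np
import pytest

from copbench import EffectProfile, SimulationConfig, simulate_trial


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def zero_config() -> SimulationConfig:
    return SimulationConfig(seed=7, effect=EffectProfile.zero())


@pytest.fixture(scope="session")
def pd_trial(default_config):
    return simulate_trial(default_config, "PD", participant_seed=0)


@pytest.fixture(scope="session")
def control_trial(default_config):
    return simulate_trial(default_config, "Control", participant_seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
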