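import numpy as np
import pytest

from latentsim import RLParams, TaskConfig, simulate_agent


@pytest.fixture(scope="session")
def choice_data():
    """A moderately long instrumental dataset with known parameters."""
    task = TaskConfig(n_trials=500)
    return simulate_agent(task, RLParams(alpha=0.1, beta=2.0), seed=123)


@pytest.fixture(scope="session")
def short_choice_data():
    task = TaskConfig(n_trials=80)
    return simulate_agent(task, RLParams(alpha=0.2, beta=1.5), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
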