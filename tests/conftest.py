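import pytest

from odortrain import agents, default_config, run_task_session


@pytest.fixture
def dnms_config():
    return default_config("DNMS")


@pytest.fixture
def perfect_dnms_session(dnms_config):
    """One balanced DNMS session from an agent that licks iff the trial is go."""
    agent = agents.bernoulli_agent({"go": 1.0, "nogo": 0.0})
    return run_task_session(dnms_config, agent, seed=7, n_trials=48)
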