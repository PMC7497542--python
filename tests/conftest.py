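import numpy as np
import pandas as pd
import pytest

from twostep_eeg import REFERENCE_PARAMS, TaskConfig, simulate_agent


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def sim_session(config):
    """One full simulated session (4 blocks x 100 trials) at the reference
    parameters; shared read-only across tests."""
    df, rpes = simulate_agent(REFERENCE_PARAMS, config, seed=11)
    return df, rpes


@pytest.fixture()
def sim_df(sim_session):
    return sim_session[0].copy()
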