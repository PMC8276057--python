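import numpy as np
import pandas as pd
import pytest

from twostep import AgentParams, TaskConfig, simulate_agent


@pytest.fixture(scope="session")
def config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def hybrid_params() -> AgentParams:
    return AgentParams(alpha=0.51, beta=5.12, w=0.51, lam=0.50, persev=0.01)


@pytest.fixture(scope="session")
def hybrid_log(config, hybrid_params) -> pd.DataFrame:
    return simulate_agent(hybrid_params, config, seed=0, subject_id="hyb")


def make_log(choices, transitions, states2, rewards, subject_id="s0"):
    """Hand-built trial log from parallel sequences."""
    n = len(choices)
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "trial": np.arange(n),
            "block": np.zeros(n, dtype=int),
            "choice": list(choices),
            "transition": list(transitions),
            "state2": list(states2),
            "reward": list(rewards),
        }
    )
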