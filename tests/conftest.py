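import numpy as np
import pandas as pd
import pytest

from latentrl import agents, task


def simulate_session(kind="rl_sd", alpha=0.4, beta=6.0, eta=0.1,
                     seed=0, n_blocks=11, session=1, **task_kwargs):
    """One session of trial records from a fresh agent, as a DataFrame."""
    rng = np.random.default_rng(seed)
    cfg = task.TaskConfig(blocks_per_session=(n_blocks,) * 3, **task_kwargs)
    agent = agents.make_agent(
        agents.AgentParams(kind=kind, alpha=alpha, beta=beta, eta=eta))
    recs = task.run_session(agent, cfg, session, rng, n_blocks=n_blocks)
    return pd.DataFrame([vars(r) for r in recs])


@pytest.fixture(scope="session")
def rl_sd_frame():
    """A 132-trial session generated by a noisy state-dependent learner."""
    return simulate_session(kind="rl_sd", alpha=0.4, beta=6.0, eta=0.1,
                            seed=7)


@pytest.fixture(scope="session")
def random_frame():
    """A session of uniformly random choices."""
    return simulate_session(kind="random", seed=11)
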