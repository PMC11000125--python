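"""Shared fixtures: small fitted decoders and a trained RL baseline agent.

The expensive artifacts (Kalman fit, PPO baseline) are session-scoped and
fully seeded so every test run sees identical objects.
"""

from __future__ import annotations

import numpy as np
import pytest

from bciadapt.env import CenterOutEnv
from bciadapt.kalman import fit_kalman_model
from bciadapt.rl import train_agent
from bciadapt.synthetic import make_tuning, passive_observation_set
from bciadapt.task import TaskConfig

RL_BASELINE_SEED = 3
RL_BASELINE_STEPS = 150_000


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def tuning(task_config):
    return make_tuning(40, seed=11)


@pytest.fixture(scope="session")
def passive_data(tuning, task_config):
    rng = np.random.default_rng(101)
    return passive_observation_set(
        tuning, task_config.target_angles, 20, task_config.cruise_speed, rng
    )


@pytest.fixture(scope="session")
def kalman_model(passive_data):
    passive, states = passive_data
    return fit_kalman_model(states, passive.counts)


@pytest.fixture(scope="session")
def rl_baseline_agent():
    """PPO agent trained to reliable success in the unrotated environment."""
    env = CenterOutEnv(seed=RL_BASELINE_SEED)
    return train_agent(env, RL_BASELINE_STEPS, seed=RL_BASELINE_SEED)
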