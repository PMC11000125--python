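"""Training, retraining and activation capture for the RL center-out agent.

The agent is trained with PPO in the unrotated environment until it reaches
reliable success, then retrained in an action-rotated environment — the RL
analog of the decoder rotation imposed on the biological subjects.  The
post-tanh activations of the policy network's second hidden layer (128
units) are recorded during rollouts and analyzed exactly like the spike
counts of the synthetic sessions.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .env import CenterOutEnv, EnvConfig
from .ppo import PPOAgent, PPOConfig, evaluate_success, ppo_train

__all__ = [
    "RolloutActivations",
    "train_agent",
    "retrain_rotated",
    "collect_activations",
    "save_agent",
    "load_agent",
]


@dataclass
class RolloutActivations:
    """Hidden-unit activations (units x steps) with per-step labels."""

    activations: np.ndarray
    target_id: np.ndarray
    condition: np.ndarray

    def __post_init__(self) -> None:
        n = self.activations.shape[1]
        if self.target_id.shape != (n,) or self.condition.shape != (n,):
            raise ValueError("labels must have one entry per recorded step")

    # alias so the manifold module can consume this like a SpikeCountMatrix
    @property
    def counts(self) -> np.ndarray:
        return self.activations

    @property
    def n_units(self) -> int:
        return self.activations.shape[0]


def train_agent(
    env: CenterOutEnv,
    total_steps: int = 300_000,
    seed: int = 0,
    config: PPOConfig | None = None,
    success_threshold: float = 0.95,
    eval_episodes: int = 200,
    log: list | None = None,
) -> PPOAgent:
    """Train a fresh PPO agent in the unrotated environment.

    Raises if the evaluated success rate stays below ``success_threshold``.
    """
    if env.theta_deg != 0.0:
        raise ValueError("baseline training requires the unrotated environment")
    agent = PPOAgent(env.observation_dim, env.action_dim, config or PPOConfig(), seed)
    ppo_train(agent, env, total_steps, seed=seed, log=log)
    rate = evaluate_success(
        agent, CenterOutEnv(env.config, 0.0, seed=seed + 1), eval_episodes, seed=seed
    )
    if rate < success_threshold:
        raise RuntimeError(
            f"training did not reach reliable success: {rate:.2%} < "
            f"{success_threshold:.0%} after {total_steps} steps"
        )
    return agent


def retrain_rotated(
    agent: PPOAgent,
    theta_deg: float,
    total_steps: int = 150_000,
    seed: int = 0,
    env_config: EnvConfig | None = None,
    success_threshold: float = 0.95,
    eval_episodes: int = 200,
    reset_exploration: bool = True,
    log: list | None = None,
) -> PPOAgent:
    """Continue optimizing a trained policy in the theta-rotated environment.

    Returns a retrained copy; the input agent is left untouched.  By default
    the retraining phase starts with fresh exploration: the policy's log
    standard deviation is reset to its initial value (after baseline
    convergence it has collapsed, and a confidently wrong near-deterministic
    policy cannot discover the rotated solution within a modest step budget)
    and the Adam moment estimates are reinitialized (moments accumulated at
    the old optimum systematically misdirect the first updates of the new
    phase).
    """
    retrained = copy.deepcopy(agent)
    if reset_exploration:
        retrained.log_std = np.full_like(
            retrained.log_std, retrained.config.init_log_std
        )
        from .ppo import Adam

        retrained._opt_pi = Adam(
            retrained.policy.params + [retrained.log_std], lr=retrained.config.lr
        )
        retrained._opt_v = Adam(retrained.value.params, lr=retrained.config.lr)
    env = CenterOutEnv(env_config, theta_deg, seed=seed + 17)
    ppo_train(retrained, env, total_steps, seed=seed, log=log)
    rate = evaluate_success(
        retrained,
        CenterOutEnv(env_config, theta_deg, seed=seed + 29),
        eval_episodes,
        seed=seed,
    )
    if rate < success_threshold:
        raise RuntimeError(
            f"retraining at theta={theta_deg:+g} deg did not reach reliable "
            f"success: {rate:.2%} < {success_threshold:.0%} after {total_steps} steps"
        )
    return retrained


def collect_activations(
    agent: PPOAgent,
    env: CenterOutEnv,
    episodes_per_target: int = 20,
    deterministic_actions: bool = True,
    condition: str = "",
    seed: int = 0,
) -> RolloutActivations:
    """Record last-hidden-layer policy activations at every rollout step."""
    if episodes_per_target < 1:
        raise ValueError("episodes_per_target must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xAC7]))
    acts, tids = [], []
    label = condition or f"theta{env.theta_deg:+g}"
    for rep in range(episodes_per_target):
        for tid in range(env.config.n_targets):
            obs = env.reset(target_id=tid)
            done = False
            while not done:
                acts.append(agent.hidden_activations(obs)[0])
                action, _ = agent.act(obs, rng, deterministic=deterministic_actions)
                obs, _, done, _ = env.step(action)
                tids.append(tid)
    activations = np.array(acts).T
    n = activations.shape[1]
    return RolloutActivations(
        activations=activations,
        target_id=np.array(tids),
        condition=np.full(n, label, dtype=object),
    )


def save_agent(agent: PPOAgent, path: str | Path) -> None:
    """Serialize an agent to JSON (nested lists; lossless at float precision)."""
    payload = {
        "config": vars(agent.config),
        "policy": [p.tolist() for p in agent.policy.params],
        "value": [p.tolist() for p in agent.value.params],
        "log_std": agent.log_std.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_agent(path: str | Path) -> PPOAgent:
    payload = json.loads(Path(path).read_text())
    cfg = PPOConfig(**payload["config"])
    obs_dim = len(payload["policy"][0][0])
    act_dim = len(payload["log_std"])
    agent = PPOAgent(obs_dim, act_dim, cfg, seed=0)
    agent.policy.params = [np.array(p) for p in payload["policy"]]
    agent.value.params = [np.array(p) for p in payload["value"]]
    agent.log_std = np.array(payload["log_std"])
    return agent
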