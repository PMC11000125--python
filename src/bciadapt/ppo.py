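"""Minimal proximal policy optimization in numpy.

Actor-critic with separate policy and value networks, each a fully
connected tanh MLP with two 128-unit hidden layers; diagonal Gaussian
policy with a state-independent learnable log standard deviation.
Training uses the clipped surrogate objective, generalized advantage
estimation, advantage normalization per batch, and Adam.

The second hidden layer's post-tanh activations of the policy network are
exposed for the manifold analysis (the analog of the recorded firing
rates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PPOConfig", "MLP", "PPOAgent", "ppo_train", "evaluate_success"]


def _orthogonal(rng: np.random.Generator, shape: tuple[int, int], gain: float):
    a = rng.standard_normal(shape)
    q, r = np.linalg.qr(a if shape[0] >= shape[1] else a.T)
    q = q * np.sign(np.diag(r))
    if shape[0] < shape[1]:
        q = q.T
    # C-contiguous so a JSON round trip reproduces BLAS results bit-exactly
    return np.ascontiguousarray(gain * q[: shape[0], : shape[1]])


class MLP:
    """Two-hidden-layer tanh MLP with orthogonal init and manual backprop."""

    def __init__(self, sizes, rng, out_gain=0.01):
        self.params = []
        n = len(sizes) - 1
        for i in range(n):
            gain = out_gain if i == n - 1 else np.sqrt(2.0)
            w = _orthogonal(rng, (sizes[i + 1], sizes[i]), gain)
            b = np.zeros(sizes[i + 1])
            self.params.extend([w, b])

    def forward(self, x: np.ndarray, return_cache: bool = False):
        """x: batch x in_dim. Returns output (batch x out_dim) [and cache]."""
        h = np.atleast_2d(x)
        cache = [h]
        n_layers = len(self.params) // 2
        for i in range(n_layers):
            w, b = self.params[2 * i], self.params[2 * i + 1]
            z = h @ w.T + b
            h = np.tanh(z) if i < n_layers - 1 else z
            cache.append(h)
        return (h, cache) if return_cache else h

    def hidden_activations(self, x: np.ndarray) -> np.ndarray:
        """Post-tanh activations of the last hidden layer (batch x width)."""
        _, cache = self.forward(x, return_cache=True)
        return cache[-2]

    def backward(self, cache, grad_out: np.ndarray):
        """Gradients of a scalar loss wrt params given d loss / d output."""
        n_layers = len(self.params) // 2
        grads = [None] * len(self.params)
        g = grad_out
        for i in reversed(range(n_layers)):
            w = self.params[2 * i]
            h_in, h_out = cache[i], cache[i + 1]
            if i < n_layers - 1:  # undo tanh
                g = g * (1.0 - h_out**2)
            grads[2 * i] = g.T @ h_in
            grads[2 * i + 1] = g.sum(axis=0)
            if i > 0:
                g = g @ w
        return grads


class Adam:
    def __init__(self, params, lr=3e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


@dataclass
class PPOConfig:
    hidden: int = 128
    lr: float = 3e-4
    gamma: float = 0.99
    gae_lambda: float = 0.95
    clip_range: float = 0.2
    n_steps: int = 2048
    batch_size: int = 64
    n_epochs: int = 10
    init_log_std: float = 0.0
    obs_scale: float = 0.1
    max_grad_norm: float = 0.5


class PPOAgent:
    """Gaussian policy + value function over the center-out observation."""

    def __init__(self, obs_dim: int, action_dim: int, config: PPOConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        h = config.hidden
        self.policy = MLP([obs_dim, h, h, action_dim], rng, out_gain=0.01)
        self.value = MLP([obs_dim, h, h, 1], rng, out_gain=1.0)
        self.log_std = np.full(action_dim, config.init_log_std)
        self._opt_pi = Adam(self.policy.params + [self.log_std], lr=config.lr)
        self._opt_v = Adam(self.value.params, lr=config.lr)

    # --- inference -------------------------------------------------------
    def _feat(self, obs: np.ndarray) -> np.ndarray:
        return np.atleast_2d(obs) * self.config.obs_scale

    def action_mean(self, obs: np.ndarray) -> np.ndarray:
        return self.policy.forward(self._feat(obs))

    def act(self, obs: np.ndarray, rng: np.random.Generator, deterministic=False):
        mean = self.action_mean(obs)[0]
        if deterministic:
            return mean, mean
        std = np.exp(self.log_std)
        return mean + std * rng.standard_normal(mean.shape), mean

    def state_value(self, obs: np.ndarray) -> np.ndarray:
        return self.value.forward(self._feat(obs))[:, 0]

    def log_prob(self, mean: np.ndarray, actions: np.ndarray) -> np.ndarray:
        std = np.exp(self.log_std)
        z = (actions - mean) / std
        return -0.5 * np.sum(z**2, axis=1) - np.sum(self.log_std) - mean.shape[
            1
        ] / 2.0 * np.log(2 * np.pi)

    def hidden_activations(self, obs: np.ndarray) -> np.ndarray:
        """Last-hidden-layer (post-tanh) policy activations, batch x 128."""
        return self.policy.hidden_activations(self._feat(obs))

    # --- training --------------------------------------------------------
    def update(self, obs, actions, old_log_prob, advantages, returns):
        cfg = self.config
        n = obs.shape[0]
        adv = (advantages - advantages.mean()) / (advantages.std() + 1e-8)
        idx_rng = np.random.default_rng(self._opt_pi.t + 12345)
        for _ in range(cfg.n_epochs):
            perm = idx_rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                mb = perm[start : start + cfg.batch_size]
                self._update_minibatch(
                    obs[mb], actions[mb], old_log_prob[mb], adv[mb], returns[mb]
                )

    def _update_minibatch(self, obs, actions, old_lp, adv, returns):
        cfg = self.config
        feats = self._feat(obs)
        b = obs.shape[0]
        # policy
        mean, cache = self.policy.forward(feats, return_cache=True)
        std = np.exp(self.log_std)
        z = (actions - mean) / std
        lp = -0.5 * np.sum(z**2, axis=1) - np.sum(self.log_std) - mean.shape[
            1
        ] / 2.0 * np.log(2 * np.pi)
        ratio = np.exp(lp - old_lp)
        clipped = np.clip(ratio, 1 - cfg.clip_range, 1 + cfg.clip_range)
        use_unclipped = ratio * adv <= clipped * adv
        # d(-surrogate)/d lp: only where the unclipped branch is active
        dlp = np.where(use_unclipped, -ratio * adv, 0.0) / b
        dmean = dlp[:, None] * (z / std)
        dlog_std = (dlp[:, None] * (z**2 - 1.0)).sum(axis=0)
        grads = self.policy.backward(cache, dmean) + [dlog_std]
        self._clip_grads(grads)
        self._opt_pi.step(self.policy.params + [self.log_std], grads)
        # value: 0.5 MSE
        v, vcache = self.value.forward(feats, return_cache=True)
        dv = (v[:, 0] - returns)[:, None] / b
        vgrads = self.value.backward(vcache, dv)
        self._clip_grads(vgrads)
        self._opt_v.step(self.value.params, vgrads)

    def _clip_grads(self, grads):
        total = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
        if total > self.config.max_grad_norm:
            scale = self.config.max_grad_norm / (total + 1e-12)
            for g in grads:
                g *= scale


def compute_gae(rewards, values, dones, last_value, gamma, lam):
    n = len(rewards)
    adv = np.zeros(n)
    gae = 0.0
    for t in reversed(range(n)):
        next_value = last_value if t == n - 1 else values[t + 1]
        next_nonterminal = 0.0 if dones[t] else 1.0
        delta = rewards[t] + gamma * next_value * next_nonterminal - values[t]
        gae = delta + gamma * lam * next_nonterminal * gae
        adv[t] = gae
    return adv


def ppo_train(
    agent: PPOAgent,
    env,
    total_steps: int,
    seed: int = 0,
    log: list | None = None,
) -> PPOAgent:
    """Run PPO on ``env`` for ``total_steps`` environment steps (in place)."""
    cfg = agent.config
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x990]))
    obs = env.reset()
    ep_outcomes: list[bool] = []
    steps_done = 0
    while steps_done < total_steps:
        n = min(cfg.n_steps, total_steps - steps_done)
        obs_buf = np.empty((n, env.observation_dim))
        act_buf = np.empty((n, env.action_dim))
        rew_buf = np.empty(n)
        done_buf = np.empty(n, dtype=bool)
        lp_buf = np.empty(n)
        for t in range(n):
            action, mean = agent.act(obs, rng)
            lp = agent.log_prob(mean[None, :], action[None, :])[0]
            next_obs, reward, done, info = env.step(action)
            obs_buf[t] = obs
            act_buf[t] = action
            rew_buf[t] = reward
            done_buf[t] = done
            lp_buf[t] = lp
            obs = next_obs
            if done:
                ep_outcomes.append(bool(info.get("reached")))
                obs = env.reset()
        values = agent.state_value(obs_buf)
        last_value = agent.state_value(obs[None, :])[0]
        adv = compute_gae(
            rew_buf, values, done_buf, last_value, cfg.gamma, cfg.gae_lambda
        )
        returns = adv + values
        agent.update(obs_buf, act_buf, lp_buf, adv, returns)
        steps_done += n
        if log is not None:
            recent = ep_outcomes[-50:]
            log.append(
                {
                    "steps": steps_done,
                    "episodes": len(ep_outcomes),
                    "recent_success": float(np.mean(recent)) if recent else 0.0,
                }
            )
    return agent


def evaluate_success(
    agent: PPOAgent,
    env,
    n_episodes: int = 200,
    seed: int = 0,
    deterministic: bool = True,
) -> float:
    """Fraction of episodes that reach the target, cycling targets evenly."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xEA1]))
    successes = 0
    n_targets = env.config.n_targets
    for ep in range(n_episodes):
        obs = env.reset(target_id=ep % n_targets)
        done = False
        reached = False
        while not done:
            action, _ = agent.act(obs, rng, deterministic=deterministic)
            obs, _, done, info = env.step(action)
            reached = info["reached"]
        successes += int(reached)
    return successes / n_episodes
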