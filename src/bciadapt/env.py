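"""Virtual center-out reaching environment for the RL agent.

Dimensionless dynamics with a leaky velocity and direct action forcing:

    v_{t+1} = 0.1 * v_t + action
    x_{t+1} = x_t + dt * v_{t+1}          (dt = 1)

The reward penalizes increases in cursor-target distance and the squared
action magnitude, and grants +20 on reaching the target:

    reward = [20 if reached] - 0.5 * delta_d - |action|^2

where delta_d is the change in cursor-target distance produced by the
step.  A rotated variant multiplies the agent's action by R(theta) before
applying the dynamics, emulating the decoder rotation of the biological
task.

The interface follows the familiar reset()/step() gym convention but the
class is self-contained (pure numpy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kalman import rotation_matrix

__all__ = ["EnvConfig", "EnvState", "CenterOutEnv"]


@dataclass(frozen=True)
class EnvConfig:
    """Constants of the virtual task; defaults are the printed model values."""

    dt: float = 1.0
    velocity_decay: float = 0.1
    n_targets: int = 8
    target_distance: float = 10.0
    target_radius: float = 1.0
    max_steps: int = 100
    success_reward: float = 20.0
    distance_coeff: float = 0.5
    action_penalty_coeff: float = 1.0
    max_action_norm: float = 5.0
    # if False, positions update with the pre-step velocity instead
    position_uses_new_velocity: bool = True

    @property
    def target_angles(self) -> np.ndarray:
        return np.deg2rad(np.arange(self.n_targets) * (360.0 / self.n_targets))

    def target_position(self, target_id: int) -> np.ndarray:
        ang = self.target_angles[target_id]
        return self.target_distance * np.array([np.cos(ang), np.sin(ang)])


@dataclass
class EnvState:
    cursor_position: np.ndarray
    cursor_velocity: np.ndarray
    target_id: int
    target_position: np.ndarray
    step_count: int = 0


class CenterOutEnv:
    """Center-out task with an optional action rotation of ``theta_deg``."""

    def __init__(
        self,
        config: EnvConfig | None = None,
        theta_deg: float = 0.0,
        seed: int | None = None,
    ):
        self.config = config or EnvConfig()
        self.theta_deg = float(theta_deg)
        self._rot = rotation_matrix(np.deg2rad(self.theta_deg))
        self.rng = np.random.default_rng(seed)
        self.state: EnvState | None = None

    @property
    def observation_dim(self) -> int:
        return 6

    @property
    def action_dim(self) -> int:
        return 2

    def observation(self) -> np.ndarray:
        """(cursor position, cursor velocity, target - cursor): 6 numbers."""
        s = self.state
        return np.concatenate(
            [s.cursor_position, s.cursor_velocity, s.target_position - s.cursor_position]
        )

    def reset(self, target_id: int | None = None) -> np.ndarray:
        cfg = self.config
        if target_id is None:
            target_id = int(self.rng.integers(cfg.n_targets))
        elif not 0 <= target_id < cfg.n_targets:
            raise ValueError(f"target_id must be in [0, {cfg.n_targets})")
        self.state = EnvState(
            cursor_position=np.zeros(2),
            cursor_velocity=np.zeros(2),
            target_id=int(target_id),
            target_position=cfg.target_position(int(target_id)),
        )
        return self.observation()

    def step(self, action: np.ndarray) -> tuple[np.ndarray, float, bool, dict]:
        if self.state is None:
            raise RuntimeError("call reset() before step()")
        action = np.asarray(action, dtype=float)
        if action.shape != (2,) or not np.all(np.isfinite(action)):
            raise ValueError("action must be a finite 2-vector")
        cfg = self.config
        norm = np.linalg.norm(action)
        if norm > cfg.max_action_norm:
            action = action * (cfg.max_action_norm / norm)
        effective = self._rot @ action
        s = self.state
        old_dist = float(np.linalg.norm(s.target_position - s.cursor_position))
        new_vel = cfg.velocity_decay * s.cursor_velocity + effective
        vel_for_pos = new_vel if cfg.position_uses_new_velocity else s.cursor_velocity
        new_pos = s.cursor_position + cfg.dt * vel_for_pos
        new_dist = float(np.linalg.norm(s.target_position - new_pos))
        delta_d = new_dist - old_dist
        reached = new_dist <= cfg.target_radius
        reward = -cfg.distance_coeff * delta_d - cfg.action_penalty_coeff * float(
            action @ action
        )
        if reached:
            reward += cfg.success_reward
        s.cursor_position = new_pos
        s.cursor_velocity = new_vel
        s.step_count += 1
        done = reached or s.step_count >= cfg.max_steps
        return self.observation(), float(reward), done, {"reached": reached}
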