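"""Closed-loop center-out BCI task.

Each trial runs the full loop per 100 ms bin: the agent forms an intent
toward the cued target (optionally re-aimed to compensate an imposed
decoder rotation), the synthetic population fires, the Kalman decoder
updates the cursor, and the trial ends when the cursor holds inside the
target for the required number of consecutive bins or times out.

A session is a schedule of blocks (baseline theta=0, then one or more
rotation blocks), each with a balanced pseudorandom target order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kalman import STATE_DIM, KalmanModel, RotationPerturbation, decode_step
from .synthetic import (
    AdaptationPolicy,
    IntentState,
    SpikeCountMatrix,
    TuningModel,
    expected_rates,
    reaim,
    sample_spikes,
)

__all__ = [
    "TaskConfig",
    "TrialRecord",
    "SessionRecord",
    "BlockSpec",
    "run_trial",
    "run_session",
    "trial_duration_summary",
    "session_activity_matrix",
]


@dataclass(frozen=True)
class TaskConfig:
    """Center-out geometry and trial rules.

    Eight targets at uniform 45 degree separation; defaults give baseline
    reaches of roughly 1-3 s at the default cruise speed.
    """

    n_targets: int = 8
    target_distance: float = 10.0
    target_radius: float = 1.5
    hold_bins: int = 2
    max_bins_per_trial: int = 100
    bin_width: float = 0.1
    cruise_speed: float = 6.0

    def __post_init__(self) -> None:
        if self.target_radius >= self.target_distance:
            raise ValueError("target_radius must be smaller than target_distance")
        if self.hold_bins < 1:
            raise ValueError("hold_bins must be >= 1")

    @property
    def target_angles(self) -> np.ndarray:
        """Target angles in radians: {0, 45, ..., 315} degrees."""
        return np.deg2rad(np.arange(self.n_targets) * (360.0 / self.n_targets))

    def target_position(self, target_id: int) -> np.ndarray:
        ang = self.target_angles[target_id]
        return self.target_distance * np.array([np.cos(ang), np.sin(ang)])


@dataclass
class TrialRecord:
    target_id: int
    states: np.ndarray  # 5 x (duration_bins + 1), includes the initial state
    counts: np.ndarray  # units x duration_bins
    success: bool
    duration_bins: int
    theta_deg: float
    block_label: str


@dataclass
class BlockSpec:
    """One block of the session schedule."""

    theta_deg: float
    trials_per_target: int
    policy: AdaptationPolicy
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            self.label = "baseline" if self.theta_deg == 0 else f"rot{self.theta_deg:+g}"


@dataclass
class SessionRecord:
    trials: list[TrialRecord]
    kalman: KalmanModel
    tuning: TuningModel
    config: TaskConfig
    schedule: list[BlockSpec]
    seed: int | None = None

    def success_rate(self, block_label: str | None = None) -> float:
        trials = [
            t
            for t in self.trials
            if block_label is None or t.block_label == block_label
        ]
        if not trials:
            raise ValueError(f"no trials in block {block_label!r}")
        return float(np.mean([t.success for t in trials]))

    @property
    def block_labels(self) -> list[str]:
        return [b.label for b in self.schedule]


def run_trial(
    config: TaskConfig,
    tuning: TuningModel,
    kalman: KalmanModel,
    policy: AdaptationPolicy,
    target_id: int,
    rng: np.random.Generator,
    theta_deg: float = 0.0,
    block_label: str = "",
) -> TrialRecord:
    """One closed-loop trial from the center to the cued target.

    The intent is a feedback policy: each bin the agent aims from the current
    cursor position toward the target at cruise speed (zero intent once inside
    the target), then applies the re-aim rotation.
    """
    if not 0 <= target_id < config.n_targets:
        raise ValueError(f"target_id must be in [0, {config.n_targets})")
    perturb = RotationPerturbation(theta_deg) if theta_deg != 0 else None
    target = config.target_position(target_id)
    x = np.zeros(STATE_DIM)
    x[4] = 1.0
    states = [x.copy()]
    counts = []
    consecutive_in = 0
    success = False
    for _ in range(config.max_bins_per_trial):
        to_target = target - x[0:2]
        dist = float(np.linalg.norm(to_target))
        if dist > config.target_radius:
            direction = float(np.arctan2(to_target[1], to_target[0]))
            intent = IntentState.from_polar(direction, config.cruise_speed)
        else:
            intent = IntentState(np.zeros(2))
        intent = reaim(intent, policy)
        y = sample_spikes(expected_rates(tuning, intent), tuning.bin_width, rng)
        x = decode_step(kalman, x, y.astype(float), perturb)
        states.append(x.copy())
        counts.append(y)
        if np.linalg.norm(target - x[0:2]) <= config.target_radius:
            consecutive_in += 1
            if consecutive_in >= config.hold_bins:
                success = True
                break
        else:
            consecutive_in = 0
    return TrialRecord(
        target_id=target_id,
        states=np.array(states).T,
        counts=np.array(counts).T,
        success=success,
        duration_bins=len(counts),
        theta_deg=theta_deg,
        block_label=block_label,
    )


def run_session(
    config: TaskConfig,
    tuning: TuningModel,
    kalman: KalmanModel,
    schedule: list[BlockSpec],
    rng: np.random.Generator | int | None = None,
) -> SessionRecord:
    """Run the scheduled blocks; targets are cycled in balanced shuffled order."""
    if not schedule:
        raise ValueError("session schedule must not be empty")
    seed = rng if isinstance(rng, int) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    trials: list[TrialRecord] = []
    for block in schedule:
        for _ in range(block.trials_per_target):
            order = rng.permutation(config.n_targets)
            for tid in order:
                trials.append(
                    run_trial(
                        config,
                        tuning,
                        kalman,
                        block.policy,
                        int(tid),
                        rng,
                        theta_deg=block.theta_deg,
                        block_label=block.label,
                    )
                )
    return SessionRecord(
        trials=trials,
        kalman=kalman,
        tuning=tuning,
        config=config,
        schedule=list(schedule),
        seed=seed,
    )


def trial_duration_summary(session: SessionRecord) -> pd.DataFrame:
    """Mean and sd of successful-trial durations (seconds) per block.

    Blocks with zero successful trials are excluded with a warning.
    """
    rows = []
    for block in session.schedule:
        durs = [
            t.duration_bins * session.config.bin_width
            for t in session.trials
            if t.block_label == block.label and t.success
        ]
        if not durs:
            warnings.warn(
                f"block {block.label!r} has no successful trials; excluded "
                "from the duration summary"
            )
            continue
        rows.append(
            {
                "block": block.label,
                "theta_deg": block.theta_deg,
                "n_success": len(durs),
                "mean_duration_s": float(np.mean(durs)),
                "sd_duration_s": float(np.std(durs, ddof=1)) if len(durs) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def session_activity_matrix(
    session: SessionRecord,
    block_label: str | None = None,
    successful_only: bool = True,
) -> SpikeCountMatrix:
    """Concatenate per-bin spike counts of (by default successful) trials.

    This is the units x observations matrix the manifold analysis consumes;
    each bin is one observation labeled by target and block.
    """
    counts, tids, trids, conds = [], [], [], []
    for i, t in enumerate(session.trials):
        if block_label is not None and t.block_label != block_label:
            continue
        if successful_only and not t.success:
            continue
        counts.append(t.counts)
        n = t.counts.shape[1]
        tids.append(np.full(n, t.target_id))
        trids.append(np.full(n, i))
        conds.append(np.full(n, t.block_label, dtype=object))
    if not counts:
        raise ValueError(f"no qualifying trials for block {block_label!r}")
    return SpikeCountMatrix(
        counts=np.hstack(counts),
        bin_width=session.config.bin_width,
        target_id=np.concatenate(tids),
        trial_id=np.concatenate(trids),
        condition=np.concatenate(conds),
    )
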