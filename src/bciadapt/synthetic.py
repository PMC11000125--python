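"""Synthetic cosine-tuned spiking population.

This module generates the spike-count observations that stand in for motor
cortical recordings in the closed-loop cursor simulations.  Each unit is
cosine tuned to intended movement direction with a multiplicative speed
gain,

    rate_i = baseline_i + modulation_i * speed_gain * speed * cos(phi - pd_i),

with rates in Hz and counts drawn Poisson per time bin.  Because
``speed * cos(phi - pd_i)`` is the projection of the intended velocity onto
the unit's preferred axis, the expected rates are exactly linear in
intended velocity, which is what makes a linear (Kalman) observation model
a faithful readout of this population.

Also provided: passive-observation data (prescribed straight cursor
trajectories paired with sampled counts) used to fit the decoder's
observation model, and the re-aiming policy that models compensation for
an imposed decoder rotation by counter-rotating the intended direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TuningModel",
    "IntentState",
    "AdaptationPolicy",
    "SpikeCountMatrix",
    "make_tuning",
    "expected_rates",
    "sample_spikes",
    "passive_observation_set",
    "reaim",
    "straight_reach_states",
]


@dataclass(frozen=True)
class TuningModel:
    """Cosine-tuning parameters of a synthetic population.

    ``baseline`` and ``modulation`` are per-unit rates in Hz; ``preferred_direction``
    is in radians in [0, 2pi).  ``speed_gain`` couples intended speed (workspace
    units/s) to modulation depth; at ``max_speed`` the full ``modulation`` is
    reached.  Non-negativity of every rate is guaranteed by the construction
    invariant baseline >= modulation * speed_gain * max_speed.
    """

    n_units: int
    baseline: np.ndarray
    modulation: np.ndarray
    preferred_direction: np.ndarray
    speed_gain: float
    max_speed: float
    bin_width: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("baseline", "modulation", "preferred_direction"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.n_units,):
                raise ValueError(f"{name} must have shape ({self.n_units},)")
            object.__setattr__(self, name, arr)
        if np.any(self.baseline < 0) or np.any(self.modulation < 0):
            raise ValueError("baseline and modulation rates must be non-negative")
        worst = self.modulation * self.speed_gain * self.max_speed
        if np.any(self.baseline - worst < -1e-9):
            raise ValueError(
                "non-negativity invariant violated: require "
                "baseline >= modulation * speed_gain * max_speed for every unit"
            )


@dataclass(frozen=True)
class IntentState:
    """Intended 2-D velocity with its polar decomposition."""

    intended_velocity: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.intended_velocity, dtype=float)
        if v.shape != (2,):
            raise ValueError("intended_velocity must be a 2-vector")
        object.__setattr__(self, "intended_velocity", v)

    @property
    def intended_direction(self) -> float:
        return float(np.arctan2(self.intended_velocity[1], self.intended_velocity[0]))

    @property
    def intended_speed(self) -> float:
        return float(np.linalg.norm(self.intended_velocity))

    @classmethod
    def from_polar(cls, direction: float, speed: float) -> "IntentState":
        if speed < 0:
            raise ValueError("speed must be non-negative")
        return cls(np.array([speed * np.cos(direction), speed * np.sin(direction)]))


@dataclass(frozen=True)
class AdaptationPolicy:
    """Re-aiming compensation for an imposed decoder rotation.

    ``compensation_fraction`` in [0, 1]: 0 means no compensation (the agent
    keeps aiming at the target), 1 means full compensation (the agent re-aims
    by the negative of the imposed rotation, the strategy the adapted subjects
    exhibit).  ``imposed_rotation`` is the decoder rotation theta in radians.
    """

    compensation_fraction: float = 0.0
    imposed_rotation: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.compensation_fraction <= 1.0:
            raise ValueError("compensation_fraction must be in [0, 1]")

    @property
    def reaim_angle(self) -> float:
        """Effective aim offset: -fraction * theta (radians)."""
        return -self.compensation_fraction * self.imposed_rotation


@dataclass
class SpikeCountMatrix:
    """Per-bin spike counts (units x bins) with per-bin labels."""

    counts: np.ndarray
    bin_width: float
    target_id: np.ndarray
    trial_id: np.ndarray
    condition: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be units x bins")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")
        n_bins = self.counts.shape[1]
        for name in ("target_id", "trial_id", "condition"):
            lab = np.asarray(getattr(self, name))
            if lab.shape != (n_bins,):
                raise ValueError(f"{name} must have one entry per bin")
            setattr(self, name, lab)

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


def make_tuning(
    n_units: int = 40,
    seed: int | None = None,
    baseline_range: tuple[float, float] = (5.0, 25.0),
    modulation_range: tuple[float, float] = (5.0, 15.0),
    speed_gain: float = 0.1,
    max_speed: float = 10.0,
    bin_width: float = 0.1,
) -> TuningModel:
    """Draw a random cosine-tuned population.

    Preferred directions are uniform on the circle; baseline and modulation
    rates are uniform on the given ranges (Hz).  Modulation is clipped so the
    worst-case rate (movement anti-preferred at ``max_speed``) stays
    non-negative.  At least 3 units with non-collinear preferred directions
    are needed for a 2-D intent to be observable from the rates.
    """
    if n_units < 3:
        raise ValueError(
            "n_units must be >= 3: observing a 2-D intent (direction and speed) "
            "requires at least 3 non-collinear tuned units"
        )
    rng = np.random.default_rng(seed)
    baseline = rng.uniform(*baseline_range, size=n_units)
    modulation = rng.uniform(*modulation_range, size=n_units)
    pd = rng.uniform(0.0, 2.0 * np.pi, size=n_units)
    # enforce non-negativity: clip modulation depth at baseline / (gain * max_speed)
    cap = baseline / (speed_gain * max_speed)
    modulation = np.minimum(modulation, cap)
    return TuningModel(
        n_units=n_units,
        baseline=baseline,
        modulation=modulation,
        preferred_direction=pd,
        speed_gain=speed_gain,
        max_speed=max_speed,
        bin_width=bin_width,
        seed=seed,
    )


def expected_rates(model: TuningModel, intent: IntentState) -> np.ndarray:
    """Per-unit expected firing rate (Hz) for an intended movement.

    Equivalent to baseline + modulation * speed_gain * (v . u_pd), i.e. linear
    in the intended velocity vector.
    """
    v = intent.intended_velocity
    proj = v[0] * np.cos(model.preferred_direction) + v[1] * np.sin(
        model.preferred_direction
    )
    rates = model.baseline + model.modulation * model.speed_gain * proj
    # the construction invariant guarantees this up to round-off
    return np.maximum(rates, 0.0)


def sample_spikes(
    rates: np.ndarray, bin_width: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson spike counts for one bin given per-unit rates in Hz."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    return rng.poisson(rates * bin_width)


def reaim(intent_toward_target: IntentState, policy: AdaptationPolicy) -> IntentState:
    """Rotate the intended direction by the policy's re-aim angle; speed unchanged."""
    return IntentState.from_polar(
        intent_toward_target.intended_direction + policy.reaim_angle,
        intent_toward_target.intended_speed,
    )


def straight_reach_states(
    target_angle: float,
    target_distance: float,
    speed: float,
    bin_width: float,
    hold_bins: int = 3,
) -> np.ndarray:
    """Prescribed cursor states for one straight center-out reach.

    Returns a 5 x bins array of [px, py, vx, vy, 1] states: constant-speed
    travel from the center to the target followed by ``hold_bins`` stationary
    bins at the endpoint.
    """
    n_move = max(1, int(np.ceil(target_distance / (speed * bin_width))))
    u = np.array([np.cos(target_angle), np.sin(target_angle)])
    t = np.arange(n_move) * bin_width
    pos_move = np.minimum(speed * t, target_distance)[:, None] * u[None, :]
    vel_move = np.tile(speed * u, (n_move, 1))
    pos_hold = np.tile(target_distance * u, (hold_bins, 1))
    vel_hold = np.zeros((hold_bins, 2))
    pos = np.vstack([pos_move, pos_hold])
    vel = np.vstack([vel_move, vel_hold])
    ones = np.ones((pos.shape[0], 1))
    return np.hstack([pos, vel, ones]).T


def passive_observation_set(
    model: TuningModel,
    target_angles: np.ndarray,
    n_reaches: int,
    speed: float,
    rng: np.random.Generator,
    target_distance: float = 10.0,
    hold_bins: int = 3,
) -> tuple[SpikeCountMatrix, np.ndarray]:
    """Passive-observation data for decoder fitting.

    The cursor moves along prescribed straight trajectories to each target
    while the population fires according to an intent equal to the prescribed
    velocity.  Returns the sampled counts and the matching 5 x bins state
    sequence.
    """
    target_angles = np.atleast_1d(np.asarray(target_angles, dtype=float))
    if target_angles.size == 0:
        raise ValueError("target set must not be empty")
    if n_reaches < 1:
        raise ValueError("need at least one reach per target")
    states_list, counts_list, tid_list = [], [], []
    for rep in range(n_reaches):
        for tid, ang in enumerate(target_angles):
            states = straight_reach_states(
                ang, target_distance, speed, model.bin_width, hold_bins
            )
            n_bins = states.shape[1]
            counts = np.empty((model.n_units, n_bins), dtype=np.int64)
            for b in range(n_bins):
                intent = IntentState(states[2:4, b])
                counts[:, b] = sample_spikes(
                    expected_rates(model, intent), model.bin_width, rng
                )
            states_list.append(states)
            counts_list.append(counts)
            tid_list.append(np.full(n_bins, tid))
    states_all = np.hstack(states_list)
    counts_all = np.hstack(counts_list)
    tids = np.concatenate(tid_list)
    n_bins_total = counts_all.shape[1]
    reps = np.repeat(
        np.arange(n_reaches * target_angles.size),
        [s.shape[1] for s in states_list],
    )
    matrix = SpikeCountMatrix(
        counts=counts_all,
        bin_width=model.bin_width,
        target_id=tids,
        trial_id=reps,
        condition=np.full(n_bins_total, "passive", dtype=object),
    )
    return matrix, states_all
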