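"""Prebuilt experiment recipes composing the simulator and the analysis.

These functions reproduce the study's main quantitative results from
scratch: pooled adjacent-centroid gap distributions from baseline
sessions, the centroid angular-displacement regression for the
full-compensation re-aiming agent, and the separate-basis manifold
preservation statistics for both the biological-style agent and the RL
agent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import manifold as mf
from .kalman import fit_kalman_model
from .synthetic import AdaptationPolicy, make_tuning, passive_observation_set
from .task import (
    BlockSpec,
    SessionRecord,
    TaskConfig,
    run_session,
    session_activity_matrix,
)

__all__ = [
    "simulate_session",
    "session_condition_matrices",
    "session_mean_displacement",
    "adjacent_gap_experiment",
    "displacement_regression_experiment",
    "preservation_experiment",
]

BASELINE = "baseline"
ROTATED = "rotated"


def simulate_session(
    seed: int,
    theta_deg: float = 0.0,
    compensation: float = 1.0,
    n_units: int = 40,
    trials_per_target: int = 20,
    config: TaskConfig | None = None,
    passive_reaches_per_target: int = 20,
) -> SessionRecord:
    """One full synthetic session: passive decoder fit, baseline block,
    and (if theta != 0) a rotation block with the given re-aiming fraction.

    All randomness derives from ``seed``.
    """
    config = config or TaskConfig()
    tuning = make_tuning(n_units, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBC1]))
    passive, states = passive_observation_set(
        tuning,
        config.target_angles,
        passive_reaches_per_target,
        config.cruise_speed,
        rng,
        target_distance=config.target_distance,
    )
    kalman = fit_kalman_model(
        states, passive.counts, bin_width=config.bin_width,
        meta={"seed": seed, "n_units": n_units},
    )
    schedule = [BlockSpec(0.0, trials_per_target, AdaptationPolicy(), label=BASELINE)]
    if theta_deg != 0.0:
        schedule.append(
            BlockSpec(
                theta_deg,
                trials_per_target,
                AdaptationPolicy(compensation, np.deg2rad(theta_deg)),
                label=ROTATED,
            )
        )
    return run_session(config, tuning, kalman, schedule, rng=rng)


def session_condition_matrices(
    session: SessionRecord,
) -> dict[str, mf.ActivityMatrix]:
    """Per-block activity matrices (successful trials only)."""
    return {
        b.label: mf.ActivityMatrix.from_spike_counts(
            session_activity_matrix(session, b.label)
        )
        for b in session.schedule
    }


def session_mean_displacement(session: SessionRecord) -> float:
    """Mean centroid angular displacement, rotated vs baseline block.

    Shared PCA basis over both blocks, oriented to the task by the baseline
    centroids; circular mean over the 8 targets, in signed degrees.
    """
    mats = session_condition_matrices(session)
    before, after = mats[BASELINE], mats[ROTATED]
    pooled = mf.ActivityMatrix(
        np.hstack([before.values, after.values]),
        np.concatenate([before.target_id, after.target_id]),
        np.concatenate([before.condition, after.condition]),
    )
    basis = mf.ensure_task_orientation(mf.fit_pca(pooled), before)
    cents_b = mf.target_centroids(mf.project(basis, before), before.target_id)
    cents_a = mf.target_centroids(mf.project(basis, after), after.target_id)
    return mf.centroid_angular_displacement(cents_b, cents_a).mean_deg


def adjacent_gap_experiment(
    n_sessions: int = 10,
    seed: int = 0,
    n_units: int = 40,
    trials_per_target: int = 20,
) -> np.ndarray:
    """Pooled adjacent-centroid gaps over seeded baseline sessions (degrees)."""
    gaps = []
    for i in range(n_sessions):
        session = simulate_session(
            seed + 1000 * i, 0.0, n_units=n_units, trials_per_target=trials_per_target
        )
        mat = session_condition_matrices(session)[BASELINE]
        basis = mf.fit_pca(mat)
        cents = mf.target_centroids(mf.project(basis, mat), mat.target_id)
        gaps.append(mf.adjacent_centroid_angles(cents))
    return np.concatenate(gaps)


@dataclass
class DisplacementExperimentResult:
    thetas_deg: np.ndarray
    mean_displacement_deg: np.ndarray  # per theta, averaged over sessions
    per_session_deg: dict[float, list[float]]
    regression: mf.DisplacementRegression


def displacement_regression_experiment(
    thetas_deg=(50.0, -50.0, 90.0, -90.0, 110.0, -110.0),
    sessions_per_theta: int = 3,
    seed: int = 0,
    compensation: float = 1.0,
    n_units: int = 40,
    trials_per_target: int = 20,
) -> DisplacementExperimentResult:
    """Mean centroid displacement vs imposed rotation, with OLS fit."""
    per_session: dict[float, list[float]] = {}
    means = []
    for j, theta in enumerate(thetas_deg):
        vals = []
        for s in range(sessions_per_theta):
            session = simulate_session(
                seed + 100_000 * j + 10 * s,
                theta,
                compensation=compensation,
                n_units=n_units,
                trials_per_target=trials_per_target,
            )
            vals.append(session_mean_displacement(session))
        per_session[theta] = vals
        means.append(float(np.mean(vals)))
    thetas = np.asarray(thetas_deg, dtype=float)
    means = np.asarray(means)
    return DisplacementExperimentResult(
        thetas_deg=thetas,
        mean_displacement_deg=means,
        per_session_deg=per_session,
        regression=mf.regress_displacement(means, thetas),
    )


def preservation_experiment(
    thetas_deg=(50.0, -50.0, 90.0, -90.0, 110.0, -110.0),
    seed: int = 0,
    compensation: float = 1.0,
    n_units: int = 40,
    trials_per_target: int = 20,
) -> list[mf.SimilarityStats]:
    """Separate-basis before/after comparison for one session per rotation."""
    before, after = [], []
    for j, theta in enumerate(thetas_deg):
        session = simulate_session(
            seed + 100_000 * j + 7,
            theta,
            compensation=compensation,
            n_units=n_units,
            trials_per_target=trials_per_target,
        )
        mats = session_condition_matrices(session)
        before.append(mats[BASELINE])
        after.append(mats[ROTATED])
    return mf.manifold_preservation_report(before, after, mode="separate_basis")
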