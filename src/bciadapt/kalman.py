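"""Steady-state Kalman cursor decoder with rotation perturbations.

State vector x = [px, py, vx, vy, 1].  The decoder runs the steady-state
filter

    x_{t+1} = A x_t + K y_t,            A = (I - K C) A_tilde,

where A_tilde encodes the prescribed cursor kinematics (position integrates
velocity; velocity decays with factor alpha per bin; the constant stays 1),
C is the observation matrix fit by least squares from passive-observation
data, and K is the steady-state Kalman gain of the discrete Riccati
recursion for process noise W and observation noise Q.

A visuomotor rotation of angle theta is imposed by left-multiplying the
gain with a 5x5 block-diagonal matrix carrying the 2x2 rotation R(theta)
on the position and the velocity block:

    x_{t+1} = A x_t + R(theta) K y_t.

Public interfaces accept angles in degrees (converted internally).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "STATE_DIM",
    "KalmanModel",
    "RotationPerturbation",
    "rotation_matrix",
    "block_rotation",
    "make_kinematics",
    "make_process_noise",
    "fit_observation_model",
    "steady_state_gain",
    "derived_dynamics",
    "decode_step",
    "fit_kalman_model",
]

STATE_DIM = 5


def rotation_matrix(theta_rad: float) -> np.ndarray:
    """2x2 counter-clockwise rotation [[cos, -sin], [sin, cos]]."""
    if not np.isfinite(theta_rad):
        raise ValueError("rotation angle must be finite")
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    return np.array([[c, -s], [s, c]])


def block_rotation(theta_rad: float) -> np.ndarray:
    """5x5 block-diagonal rotation: R(theta) on position and velocity, 1 on the constant."""
    out = np.eye(STATE_DIM)
    r = rotation_matrix(theta_rad)
    out[0:2, 0:2] = r
    out[2:4, 2:4] = r
    return out


@dataclass(frozen=True)
class RotationPerturbation:
    """An imposed decoder rotation, stored in degrees at the interface."""

    theta_deg: float

    @property
    def theta_rad(self) -> float:
        return float(np.deg2rad(self.theta_deg))

    @property
    def as_matrix(self) -> np.ndarray:
        return block_rotation(self.theta_rad)


def make_kinematics(bin_width: float = 0.1, velocity_decay: float = 0.8) -> np.ndarray:
    """Prescribed-kinematics matrix A_tilde.

    Position integrates velocity over the bin; velocity persists with a
    damping factor per bin; the constant row is identity.
    """
    a = np.eye(STATE_DIM)
    a[0, 2] = bin_width
    a[1, 3] = bin_width
    a[2, 2] = velocity_decay
    a[3, 3] = velocity_decay
    return a


def make_process_noise(velocity_var: float = 1.0) -> np.ndarray:
    """Process-noise covariance W: isotropic on velocity, zero elsewhere.

    Position is a deterministic integral of velocity and the constant never
    varies, so only the velocity block carries noise.
    """
    w = np.zeros((STATE_DIM, STATE_DIM))
    w[2, 2] = velocity_var
    w[3, 3] = velocity_var
    return w


def fit_observation_model(
    passive_states: np.ndarray, passive_counts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of counts ~ C @ state; Q is the residual covariance.

    ``passive_states`` is 5 x bins (constant row included), ``passive_counts``
    is units x bins.
    """
    x = np.asarray(passive_states, dtype=float)
    y = np.asarray(passive_counts, dtype=float)
    if x.shape[0] != STATE_DIM:
        raise ValueError(f"states must be {STATE_DIM} x bins")
    n_bins = x.shape[1]
    if y.shape[1] != n_bins:
        raise ValueError("states and counts must have the same number of bins")
    if n_bins <= STATE_DIM:
        raise ValueError("need more bins than state dimensions to fit C")
    if np.linalg.matrix_rank(x) < STATE_DIM:
        raise ValueError(
            "passive state matrix is rank deficient; trajectories must excite "
            "all position and velocity components"
        )
    # solve y.T ~ x.T @ C.T
    c_t, *_ = np.linalg.lstsq(x.T, y.T, rcond=None)
    c = c_t.T
    resid = y - c @ x
    q = resid @ resid.T / n_bins
    q = 0.5 * (q + q.T)
    return c, q


def steady_state_gain(
    a_tilde: np.ndarray,
    c: np.ndarray,
    w: np.ndarray,
    q: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Steady-state Kalman gain via the discrete Riccati recursion.

    Iterates the prediction-error covariance Sigma from Sigma_0 = W until the
    Frobenius norm of the update falls below ``tol``, then returns
    K = Sigma C' (C Sigma C' + Q)^{-1}.
    """
    a_tilde = np.asarray(a_tilde, dtype=float)
    c = np.asarray(c, dtype=float)
    w = np.asarray(w, dtype=float)
    q = np.asarray(q, dtype=float)
    sigma = w.copy()
    # regularize the innovation covariance only if Q is singular
    for it in range(max_iter):
        s = c @ sigma @ c.T + q
        gain = np.linalg.solve(s.T, (sigma @ c.T).T).T  # Sigma C' S^-1
        post = sigma - gain @ c @ sigma
        new_sigma = a_tilde @ post @ a_tilde.T + w
        new_sigma = 0.5 * (new_sigma + new_sigma.T)
        delta = np.linalg.norm(new_sigma - sigma)
        sigma = new_sigma
        if delta < tol:
            s = c @ sigma @ c.T + q
            return np.linalg.solve(s.T, (sigma @ c.T).T).T
    raise RuntimeError(
        f"Riccati iteration did not converge within {max_iter} iterations "
        f"(last Frobenius update {delta:.3e} > tol {tol:.1e})"
    )


def derived_dynamics(a_tilde: np.ndarray, k: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Closed-loop dynamics A = (I - K C) A_tilde."""
    a_tilde = np.asarray(a_tilde, dtype=float)
    k = np.asarray(k, dtype=float)
    c = np.asarray(c, dtype=float)
    n = a_tilde.shape[0]
    if a_tilde.shape != (n, n) or k.shape[0] != n or c.shape[1] != n:
        raise ValueError("incompatible shapes for A_tilde, K, C")
    if k.shape[1] != c.shape[0]:
        raise ValueError("K and C disagree on the number of units")
    return (np.eye(n) - k @ c) @ a_tilde


@dataclass
class KalmanModel:
    """Fitted decoder: kinematic prior, observation model, gain, dynamics.

    ``y_mean`` is the per-unit mean count of the fitting data; observations
    are centered by it before decoding.  Centering matters once a rotation is
    imposed: rotating the gain against raw counts would rotate the large
    baseline contribution K@y_mean too, injecting a constant cursor drift
    that no re-aiming strategy could null.
    """

    a_tilde: np.ndarray
    c: np.ndarray
    q: np.ndarray
    w: np.ndarray
    k: np.ndarray
    a: np.ndarray
    y_mean: np.ndarray | None = None
    meta: dict | None = None

    def __post_init__(self) -> None:
        for name in ("a_tilde", "c", "q", "w", "k", "a"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.y_mean is None:
            self.y_mean = np.zeros(self.c.shape[0])
        self.y_mean = np.asarray(self.y_mean, dtype=float)
        if self.a_tilde.shape != (STATE_DIM, STATE_DIM):
            raise ValueError("A_tilde must be 5x5")
        resid = np.linalg.norm(
            self.a - derived_dynamics(self.a_tilde, self.k, self.c)
        )
        if resid > 1e-6:
            raise ValueError(f"A != (I - KC) A_tilde (residual {resid:.2e})")

    @property
    def n_units(self) -> int:
        return self.c.shape[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            name: getattr(self, name).tolist()
            for name in ("a_tilde", "c", "q", "w", "k", "a", "y_mean")
        }
        payload["meta"] = self.meta or {}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "KalmanModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            a_tilde=np.array(payload["a_tilde"]),
            c=np.array(payload["c"]),
            q=np.array(payload["q"]),
            w=np.array(payload["w"]),
            k=np.array(payload["k"]),
            a=np.array(payload["a"]),
            y_mean=np.array(payload["y_mean"]),
            meta=payload.get("meta") or None,
        )


def decode_step(
    model: KalmanModel,
    x_t: np.ndarray,
    y_t: np.ndarray,
    perturbation: RotationPerturbation | None = None,
) -> np.ndarray:
    """One decode update; with a perturbation the gain is rotated first.

    The constant component of the state is restored to exactly 1 afterwards.
    """
    x_t = np.asarray(x_t, dtype=float)
    y_t = np.asarray(y_t, dtype=float)
    if x_t.shape != (STATE_DIM,):
        raise ValueError("state must be a 5-vector")
    if y_t.shape != (model.n_units,):
        raise ValueError(
            f"observation must have {model.n_units} entries, got {y_t.shape}"
        )
    if abs(x_t[4] - 1.0) > 1e-9:
        raise ValueError("state constant component must be 1")
    ky = model.k @ (y_t - model.y_mean)
    if perturbation is not None:
        ky = perturbation.as_matrix @ ky
    x_next = model.a @ x_t + ky
    x_next[4] = 1.0
    return x_next


def fit_kalman_model(
    passive_states: np.ndarray,
    passive_counts: np.ndarray,
    bin_width: float = 0.1,
    velocity_decay: float = 0.8,
    velocity_noise_var: float = 1.0,
    center_observations: bool = True,
    meta: dict | None = None,
) -> KalmanModel:
    """Fit C and Q from passive data and assemble the full decoder.

    With ``center_observations`` (default) the per-unit mean count of the
    passive set is stored and subtracted at decode time, so the fitted
    constant column of C is near zero and the rotated gain acts only on the
    movement-driven part of the counts.
    """
    a_tilde = make_kinematics(bin_width, velocity_decay)
    w = make_process_noise(velocity_noise_var)
    counts = np.asarray(passive_counts, dtype=float)
    y_mean = counts.mean(axis=1) if center_observations else np.zeros(counts.shape[0])
    c, q = fit_observation_model(passive_states, counts - y_mean[:, None])
    k = steady_state_gain(a_tilde, c, w, q)
    a = derived_dynamics(a_tilde, k, c)
    return KalmanModel(
        a_tilde=a_tilde, c=c, q=q, w=w, k=k, a=a, y_mean=y_mean, meta=meta
    )
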