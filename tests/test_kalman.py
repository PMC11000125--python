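"""Decoder tests: observation fit, Riccati gain (vs oracles), decode step."""

import numpy as np
import pytest
from scipy import linalg

from bciadapt.kalman import (
    KalmanModel,
    RotationPerturbation,
    block_rotation,
    decode_step,
    derived_dynamics,
    fit_kalman_model,
    fit_observation_model,
    make_kinematics,
    make_process_noise,
    rotation_matrix,
    steady_state_gain,
)
from bciadapt.synthetic import make_tuning, passive_observation_set


class TestRotationMatrix:
    def test_identity_at_zero(self):
        np.testing.assert_allclose(rotation_matrix(0.0), np.eye(2), atol=1e-12)

    def test_quarter_turn(self):
        v = rotation_matrix(np.pi / 2) @ np.array([1.0, 0.0])
        np.testing.assert_allclose(v, [0.0, 1.0], atol=1e-12)

    def test_inverse_pair(self):
        th = np.deg2rad(50.0)
        np.testing.assert_allclose(
            rotation_matrix(th) @ rotation_matrix(-th), np.eye(2), atol=1e-12
        )

    @pytest.mark.parametrize("deg", [-110, -90, -50, 0, 50, 90, 110, 13.7])
    def test_orthonormal_determinant_one(self, deg):
        r = rotation_matrix(np.deg2rad(deg))
        np.testing.assert_allclose(r.T @ r, np.eye(2), atol=1e-12)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rotation_matrix(np.nan)

    def test_block_rotation_preserves_constant(self):
        b = block_rotation(np.deg2rad(90))
        assert b[4, 4] == 1.0
        np.testing.assert_allclose(b.T @ b, np.eye(5), atol=1e-12)


class TestObservationFit:
    def test_noise_free_exact_recovery(self):
        rng = np.random.default_rng(0)
        c0 = rng.standard_normal((12, 5))
        states = rng.standard_normal((5, 200))
        states[4] = 1.0
        c, q = fit_observation_model(states, c0 @ states)
        np.testing.assert_allclose(c, c0, atol=1e-9)
        np.testing.assert_allclose(q, 0.0, atol=1e-12)

    def test_error_shrinks_with_more_reaches(self):
        tun = make_tuning(40, seed=5)
        dt = tun.bin_width
        u = np.stack([np.cos(tun.preferred_direction), np.sin(tun.preferred_direction)])
        c_true = np.zeros((40, 5))
        c_true[:, 2:4] = (tun.modulation[:, None] * tun.speed_gain * u.T) * dt
        c_true[:, 4] = tun.baseline * dt
        errs = []
        for n_reaches, seed in [(5, 1), (80, 2)]:
            mat, states = passive_observation_set(
                tun, np.deg2rad(np.arange(8) * 45.0), n_reaches, 6.0,
                np.random.default_rng(seed),
            )
            c, _ = fit_observation_model(states, mat.counts)
            errs.append(np.linalg.norm(c - c_true))
        assert errs[1] < errs[0]

    def test_too_few_bins_rejected(self):
        states = np.ones((5, 4))
        with pytest.raises(ValueError, match="more bins"):
            fit_observation_model(states, np.ones((3, 4)))

    def test_rank_deficient_states_rejected(self):
        states = np.zeros((5, 50))
        states[4] = 1.0
        with pytest.raises(ValueError, match="rank"):
            fit_observation_model(states, np.ones((3, 50)))


def _brute_force_gain(a, c, w, q, n_iter=100_000):
    """Independent long-run Riccati iteration (the oracle)."""
    sigma = w.copy()
    for _ in range(n_iter):
        s = c @ sigma @ c.T + q
        k = sigma @ c.T @ np.linalg.inv(s)
        sigma = a @ (sigma - k @ c @ sigma) @ a.T + w
    s = c @ sigma @ c.T + q
    return sigma @ c.T @ np.linalg.inv(s)


class TestSteadyStateGain:
    def test_scalar_no_process_noise_gives_zero_gain(self):
        k = steady_state_gain(
            np.eye(1), np.eye(1), np.zeros((1, 1)), np.eye(1)
        )
        np.testing.assert_allclose(k, 0.0, atol=1e-12)

    def test_matches_brute_force_iteration(self):
        rng = np.random.default_rng(12)
        a = 0.9 * linalg.orth(rng.standard_normal((5, 5)))
        c = rng.standard_normal((7, 5))
        w = np.diag(rng.uniform(0.1, 1.0, 5))
        q = np.diag(rng.uniform(0.5, 2.0, 7))
        k = steady_state_gain(a, c, w, q)
        k_oracle = _brute_force_gain(a, c, w, q, n_iter=10_000)
        np.testing.assert_allclose(k, k_oracle, atol=1e-8)

    def test_matches_scipy_dare(self):
        rng = np.random.default_rng(21)
        a = 0.8 * linalg.orth(rng.standard_normal((5, 5)))
        c = rng.standard_normal((6, 5))
        w = np.diag(rng.uniform(0.2, 1.0, 5))
        q = np.diag(rng.uniform(0.5, 2.0, 6))
        sigma = linalg.solve_discrete_are(a.T, c.T, w, q)
        k_ref = sigma @ c.T @ np.linalg.inv(c @ sigma @ c.T + q)
        k = steady_state_gain(a, c, w, q)
        np.testing.assert_allclose(k, k_ref, atol=1e-7)

    def test_larger_observation_noise_shrinks_gain(self):
        # fixed axis-decoupled test system: each unit reads one kinematic
        # component, so noisier observations shrink every gain entry
        a = make_kinematics()
        c = np.zeros((4, 5))
        c[0, 0] = c[1, 1] = 0.05
        c[2, 2] = c[3, 3] = 1.0
        w = make_process_noise(1.0)
        q = np.eye(4)
        k1 = steady_state_gain(a, c, w, q)
        k2 = steady_state_gain(a, c, w, 100.0 * q)
        assert np.all(np.abs(k2) <= np.abs(k1) + 1e-12)

    def test_gain_is_riccati_fixed_point(self, kalman_model):
        m = kalman_model
        # recover Sigma from one more recursion starting where K satisfies
        # K = Sigma C'(C Sigma C' + Q)^-1; check stationarity directly
        sigma = m.w.copy()
        for _ in range(20_000):
            s = m.c @ sigma @ m.c.T + m.q
            k = sigma @ m.c.T @ np.linalg.inv(s)
            new = m.a_tilde @ (sigma - k @ m.c @ sigma) @ m.a_tilde.T + m.w
            if np.linalg.norm(new - sigma) < 1e-13:
                sigma = new
                break
            sigma = new
        s = m.c @ sigma @ m.c.T + m.q
        k = sigma @ m.c.T @ np.linalg.inv(s)
        one_step = m.a_tilde @ (sigma - k @ m.c @ sigma) @ m.a_tilde.T + m.w
        assert np.linalg.norm(one_step - sigma) < 1e-9

    def test_nonconvergence_raises(self):
        a = np.eye(1) * 2.0  # unstable, unobservable below
        c = np.zeros((1, 1))
        with pytest.raises(RuntimeError, match="did not converge"):
            steady_state_gain(a, c, np.eye(1), np.eye(1), max_iter=50)


class TestDerivedDynamics:
    def test_zero_gain_returns_a_tilde(self):
        a_tilde = make_kinematics()
        np.testing.assert_array_equal(
            derived_dynamics(a_tilde, np.zeros((5, 3)), np.ones((3, 5))), a_tilde
        )

    def test_full_correction_zeroes_dynamics(self):
        a_tilde = make_kinematics()
        k = np.eye(5)
        c = np.eye(5)
        np.testing.assert_allclose(derived_dynamics(a_tilde, k, c), 0.0, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            derived_dynamics(make_kinematics(), np.zeros((5, 3)), np.ones((4, 5)))


class TestDecodeStep:
    def test_zero_rotation_equals_unperturbed(self, kalman_model, tuning):
        x = np.array([1.0, 2.0, 0.5, -0.5, 1.0])
        y = np.full(tuning.n_units, 2.0)
        a = decode_step(kalman_model, x, y)
        b = decode_step(kalman_model, x, y, RotationPerturbation(0.0))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_mean_observation_gives_pure_dynamics(self, kalman_model):
        # centered observation of zero: update reduces to x' = A x
        x = np.array([1.0, -1.0, 2.0, 0.0, 1.0])
        out = decode_step(kalman_model, x, kalman_model.y_mean.copy())
        expected = kalman_model.a @ x
        expected[4] = 1.0
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_rotation_rotates_observation_contribution(self, kalman_model, tuning):
        x = np.zeros(5)
        x[4] = 1.0
        y = np.full(tuning.n_units, 3.0)
        base = decode_step(kalman_model, x, y) - decode_step(
            kalman_model, x, kalman_model.y_mean.copy()
        )
        rot = decode_step(kalman_model, x, y, RotationPerturbation(90.0)) - decode_step(
            kalman_model, x, kalman_model.y_mean.copy(), RotationPerturbation(90.0)
        )
        r90 = rotation_matrix(np.pi / 2)
        np.testing.assert_allclose(rot[0:2], r90 @ base[0:2], atol=1e-10)
        np.testing.assert_allclose(rot[2:4], r90 @ base[2:4], atol=1e-10)

    def test_rotation_preserves_velocity_speed(self, kalman_model, tuning):
        rng = np.random.default_rng(4)
        x = np.zeros(5)
        x[4] = 1.0
        for _ in range(5):
            y = rng.poisson(3.0, tuning.n_units).astype(float)
            v0 = decode_step(kalman_model, x, y)[2:4]
            for deg in (50.0, -90.0, 110.0):
                v = decode_step(kalman_model, x, y, RotationPerturbation(deg))[2:4]
                assert np.linalg.norm(v) == pytest.approx(np.linalg.norm(v0), rel=1e-9)

    def test_decode_linearity_in_observations(self, kalman_model, tuning):
        rng = np.random.default_rng(6)
        x = np.array([0.5, 0.5, 1.0, -1.0, 1.0])
        y1 = rng.poisson(3.0, tuning.n_units).astype(float)
        y2 = rng.poisson(3.0, tuning.n_units).astype(float)
        zero = np.zeros(tuning.n_units)
        f = lambda y: decode_step(kalman_model, x, y)
        lhs = f(y1 + y2) - f(zero)
        rhs = (f(y1) - f(zero)) + (f(y2) - f(zero))
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_dimension_mismatch_rejected(self, kalman_model):
        x = np.zeros(5)
        x[4] = 1.0
        with pytest.raises(ValueError):
            decode_step(kalman_model, x, np.zeros(3))

    def test_constant_component_restored(self, kalman_model, tuning):
        x = np.zeros(5)
        x[4] = 1.0
        out = decode_step(kalman_model, x, np.full(tuning.n_units, 5.0))
        assert out[4] == 1.0


class TestSerialization:
    def test_json_round_trip_lossless(self, kalman_model, tmp_path):
        p = tmp_path / "model.json"
        kalman_model.to_json(p)
        loaded = KalmanModel.from_json(p)
        for f in ("a_tilde", "c", "q", "w", "k", "a", "y_mean"):
            np.testing.assert_array_equal(getattr(loaded, f), getattr(kalman_model, f))
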