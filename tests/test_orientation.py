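"""Orientation filter: gyro integration, Gauss-Newton correction, fusion."""

import numpy as np
import pytest

from orientinv import quat, simulate
from orientinv.orientation import (FilterConfig, estimate_orientation,
                                   gauss_newton_correction, integrate_gyro,
                                   triad_init, _residual, _unit)

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def _synthetic_sample(q_true, cfg=None):
    cfg = cfg or FilterConfig()
    R = quat.rotmat_from_quat(q_true)
    acc = R.T @ np.array([0.0, 0.0, cfg.gravity])
    mag = R.T @ cfg.mag_reference
    return acc, mag


class TestIntegrateGyro:
    def test_zero_rate_is_identity(self):
        q = quat.quat_normalize([0.9, 0.1, -0.2, 0.3])
        assert np.allclose(integrate_gyro(q, [0, 0, 0], 0.04), q)

    def test_constant_rate_closed_form(self):
        # pi/2 rad/s about z for 1 s at 25 Hz -> quarter turn about z
        q = IDENTITY.copy()
        for _ in range(25):
            q = integrate_gyro(q, [0, 0, np.pi / 2], 1 / 25)
        expected = quat.quat_from_axis_angle([0, 0, 1], np.pi / 2)
        assert np.abs(q - expected).max() < 1e-3

    def test_step_halving_order(self):
        omega = np.array([0.7, -0.3, 1.1])
        q_full = integrate_gyro(IDENTITY, omega, 0.04)
        q_half = integrate_gyro(integrate_gyro(IDENTITY, omega, 0.02), omega, 0.02)
        assert quat.quat_angle_deg(q_full, q_half) < np.degrees(0.04 ** 2)

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            integrate_gyro(IDENTITY, [0, 0, 1], 0.0)


class TestGaussNewton:
    def test_reference_aligned_stays_identity(self):
        cfg = FilterConfig()
        acc = np.array([0.0, 0.0, cfg.gravity])
        q = gauss_newton_correction(IDENTITY, acc, cfg.mag_reference, cfg)
        assert quat.quat_angle_deg(q, IDENTITY) < 1e-6

    def test_converges_to_ground_truth_from_small_perturbation(self, rng):
        for _ in range(20):
            q_true = quat.quat_normalize(rng.standard_normal(4))
            acc, mag = _synthetic_sample(q_true)
            perturb = quat.quat_from_axis_angle(rng.standard_normal(3),
                                                np.radians(5.0))
            q0 = quat.quat_multiply(q_true, perturb)
            q = gauss_newton_correction(q0, acc, mag, FilterConfig(gn_max_iter=10))
            assert quat.quat_angle_deg(q, q_true) < 0.5

    def test_descent_property(self, rng):
        cfg = FilterConfig()
        for _ in range(20):
            q_true = quat.quat_normalize(rng.standard_normal(4))
            acc, mag = _synthetic_sample(q_true)
            q0 = quat.quat_normalize(rng.standard_normal(4))
            q1 = gauss_newton_correction(q0, acc, mag, cfg)
            a_hat, m_hat = _unit(acc[None]), _unit(mag[None])

            def cost(qq):
                return (_residual(qq[None], a_hat, m_hat) ** 2).sum()

            assert cost(q1) <= cost(q0) + 1e-12

    def test_parallel_acc_mag_unobservable(self):
        q0 = quat.quat_normalize([0.9, 0.1, 0.0, 0.0])
        with pytest.warns(UserWarning, match="unobservable"):
            q = gauss_newton_correction(q0, [0, 0, 9.8], [0, 0, 1.0])
        assert np.allclose(q, q0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            gauss_newton_correction(IDENTITY, [0, 0, 0], [1, 0, 0])


class TestTriad:
    def test_exact_for_clean_measurements(self, rng):
        for _ in range(20):
            q_true = quat.quat_normalize(rng.standard_normal(4))
            acc, mag = _synthetic_sample(q_true)
            q = triad_init(acc, mag)[0]
            assert quat.quat_angle_deg(q, q_true) < 1e-6


class TestFilter:
    def test_static_reference_stream_gives_identity(self):
        cfg = FilterConfig()
        n = 50
        acc = np.tile([0.0, 0.0, cfg.gravity], (n, 1))
        mag = np.tile(cfg.mag_reference, (n, 1))
        q = estimate_orientation(acc, np.zeros((n, 3)), mag, 25.0, cfg)
        assert q.shape == (n, 4)
        assert np.abs(q - IDENTITY).max() < 1e-6

    def test_recovers_simulated_trajectory(self):
        spec = simulate.default_activity_specs()[10]
        acc, gyro, mag, truth = simulate.simulate_unit(spec, duration_s=5,
                                                       seed=3, noise=False)
        q = estimate_orientation(acc, gyro, mag, 25.0)
        err = quat.quat_angle_deg(q, truth.quats)
        assert err[25:].mean() < 2.0  # after the first second

    def test_equivariance_under_constant_reorientation(self):
        spec = simulate.default_activity_specs()[6]
        acc, gyro, mag, _ = simulate.simulate_unit(spec, duration_s=5,
                                                   seed=5, noise=False)
        P = quat.random_rotation(21)
        q = estimate_orientation(acc, gyro, mag, 25.0)
        # re-worn unit: acquired data v~ = P^-1 v, estimates compose as R~ = R P
        q_rot = estimate_orientation(acc @ P, gyro @ P, mag @ P, 25.0)
        expected = quat.quat_from_rotmat(quat.rotmat_from_quat(q) @ P)
        assert quat.quat_angle_deg(expected, q_rot).max() < 2.0

    def test_mu_near_one_is_pure_gyro_integration(self):
        spec = simulate.default_activity_specs()[8]
        acc, gyro, mag, _ = simulate.simulate_unit(spec, duration_s=2,
                                                   seed=2, noise=False)
        cfg = FilterConfig(mu=1.0 - 1e-12)
        q = estimate_orientation(acc, gyro, mag, 25.0, cfg)
        # oracle: TRIAD start, then trapezoidal gyro integration (the first
        # sample carries a half-step because the prefix has zero rate)
        manual = [integrate_gyro(triad_init(acc[0], mag[0])[0],
                                 0.5 * gyro[0], 1 / 25)]
        for n in range(1, len(acc)):
            manual.append(integrate_gyro(manual[-1],
                                         0.5 * (gyro[n - 1] + gyro[n]), 1 / 25))
        manual = np.stack(manual)
        assert quat.quat_angle_deg(q, manual).max() < 1e-3

    def test_mu_near_zero_tracks_accel_mag_solution(self):
        # pure rotation, no linear acceleration: the Gauss-Newton solution is exact
        spec = simulate.MotionSpec("spin", gyro_amp=(0.5, 0.8, 0.3),
                                   gyro_freq=(0.7, 1.1, 0.9))
        acc, gyro, mag, truth = simulate.simulate_unit(spec, duration_s=3,
                                                       seed=4, noise=False)
        cfg = FilterConfig(mu=1e-6)
        q = estimate_orientation(acc, gyro, mag, 25.0, cfg)
        assert quat.quat_angle_deg(q, truth.quats).max() < 1.0

    def test_output_unit_norm_and_length(self):
        spec = simulate.default_activity_specs()[5]
        acc, gyro, mag, _ = simulate.simulate_unit(spec, duration_s=2, seed=1)
        q = estimate_orientation(acc, gyro, mag, 25.0)
        assert q.shape == (len(acc), 4)
        assert np.abs(np.linalg.norm(q, axis=1) - 1).max() < 1e-9

    def test_too_short_stream_rejected(self):
        with pytest.raises(ValueError):
            estimate_orientation(np.zeros((1, 3)), np.zeros((1, 3)),
                                 np.zeros((1, 3)), 25.0)
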