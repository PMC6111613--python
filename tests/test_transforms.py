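"""The seven pre-processing transforms and their invariance guarantees."""

import numpy as np
import pytest

from orientinv import quat, simulate
from orientinv import transforms as tr


@pytest.fixture(scope="module")
def moving_segment():
    spec = simulate.default_activity_specs()[6]
    acc, gyro, mag, truth = simulate.simulate_unit(spec, duration_s=5, seed=1)
    return tr.UnitSegment(acc, gyro, mag), truth


def _reoriented(seg: tr.UnitSegment, P: np.ndarray) -> tr.UnitSegment:
    """The same motion recorded by a unit re-worn with constant rotation P
    (acquired vectors are pre-multiplied by P)."""
    return tr.UnitSegment(seg.acc @ P.T, seg.gyro @ P.T, seg.mag @ P.T,
                          rate=seg.rate)


class TestChannelCounts:
    @pytest.mark.parametrize("technique,count", sorted(tr.CHANNELS_PER_UNIT.items()))
    def test_counts(self, moving_segment, technique, count):
        seg, truth = moving_segment
        out = tr.transform(seg, technique, quats=truth.quats, rng=0)
        assert out.channels.shape == (count, seg.n_samples)
        assert len(out.names) == count

    def test_unknown_technique(self, moving_segment):
        with pytest.raises(ValueError, match="reference"):
            tr.transform(moving_segment[0], "bogus")


class TestReference:
    def test_passthrough_and_idempotence(self, moving_segment):
        seg, _ = moving_segment
        out = tr.t_reference(seg)
        assert np.array_equal(out.channels[:3], seg.acc.T)
        assert np.array_equal(out.channels[3:6], seg.gyro.T)
        again = tr.t_reference(tr.UnitSegment(out.channels[:3].T,
                                              out.channels[3:6].T,
                                              out.channels[6:].T))
        assert np.array_equal(again.channels, out.channels)


class TestRandomRotation:
    def test_deterministic_and_consistent(self, moving_segment):
        seg, _ = moving_segment
        a = tr.t_random_rotation(seg, 42)
        b = tr.t_random_rotation(seg, 42)
        assert np.array_equal(a.channels, b.channels)
        P = quat.random_rotation(42)  # the same draw the transform makes
        assert np.allclose(a.channels[:3], (seg.acc @ P.T).T)

    def test_norms_preserved(self, moving_segment):
        seg, _ = moving_segment
        out = tr.t_random_rotation(seg, 3)
        for i, s in enumerate(seg.streams()):
            rotated = out.channels[3 * i:3 * (i + 1)].T
            assert np.allclose(np.linalg.norm(rotated, axis=1),
                               np.linalg.norm(s, axis=1))


class TestNorm:
    def test_345_triangle(self):
        seg = tr.UnitSegment(np.tile([3.0, 4.0, 0.0], (125, 1)),
                             np.zeros((125, 3)), np.ones((125, 3)))
        assert np.allclose(tr.t_norm(seg).channels[0], 5.0)

    def test_exactly_invariant_to_random_rotation(self, moving_segment):
        seg, _ = moving_segment
        rot = tr.t_random_rotation(seg, 9)
        seg_r = tr.UnitSegment(rot.channels[:3].T, rot.channels[3:6].T,
                               rot.channels[6:].T)
        assert np.allclose(tr.t_norm(seg).channels, tr.t_norm(seg_r).channels,
                           atol=1e-12)


class TestGravity:
    def test_constant_vertical_acceleration(self):
        seg = tr.UnitSegment(np.tile([0.0, 0.0, 9.8], (125, 1)),
                             np.zeros((125, 3)), np.ones((125, 3)))
        out = tr.t_gravity(seg)
        assert np.allclose(out.channels[0], 9.8)   # acc along gravity
        assert np.allclose(out.channels[1], 0.0)   # acc perpendicular

    def test_invariant_to_constant_rotation(self, moving_segment, rng):
        seg, _ = moving_segment
        P = quat.random_rotation(rng)
        assert np.allclose(tr.t_gravity(seg).channels,
                           tr.t_gravity(_reoriented(seg, P)).channels, atol=1e-9)

    def test_zero_mean_acceleration_rejected(self):
        acc = np.concatenate([np.ones((60, 3)), -np.ones((60, 3))])
        seg = tr.UnitSegment(acc, np.zeros((120, 3)), np.ones((120, 3)))
        with pytest.raises(tr.DegenerateSegmentError):
            tr.t_gravity(seg)


class TestSvd:
    def test_invariant_to_constant_rotation(self, moving_segment, rng):
        seg, _ = moving_segment
        P = quat.random_rotation(rng)
        assert np.abs(tr.t_svd(seg).channels
                      - tr.t_svd(_reoriented(seg, P)).channels).max() < 1e-9

    def test_singular_values_preserved(self, moving_segment):
        seg, _ = moving_segment
        out = tr.t_svd(seg)
        M_in = np.concatenate([s.T for s in seg.streams()], axis=1)
        M_out = out.channels.reshape(3, 3, -1).transpose(1, 0, 2).reshape(3, -1)
        s_in = np.linalg.svd(M_in, compute_uv=False)
        s_out = np.linalg.svd(M_out, compute_uv=False)
        assert np.allclose(s_in, s_out)

    def test_axis_aligned_data_recovered_up_to_sign(self, rng):
        # diagonal covariance with variances x > y > z: principal axes = +-e_i
        scale = np.array([5.0, 2.0, 0.5])
        acc = rng.standard_normal((200, 3)) * scale
        seg = tr.UnitSegment(acc, np.zeros((200, 3)), np.zeros((200, 3)))
        U, _ = tr.svd_axes(seg)
        assert np.allclose(np.abs(U), np.eye(3), atol=1e-1)

    def test_zero_data_falls_back_to_identity(self):
        seg = tr.UnitSegment(np.zeros((125, 3)), np.zeros((125, 3)),
                             np.zeros((125, 3)))
        with pytest.warns(UserWarning):
            U, s = tr.svd_axes(seg)
        assert np.array_equal(U, np.eye(3))


class TestEarth:
    def test_identity_trajectory_is_passthrough(self, moving_segment):
        seg, _ = moving_segment
        quats = np.tile([1.0, 0, 0, 0], (seg.n_samples, 1))
        assert np.allclose(tr.t_earth(seg, quats).channels,
                           tr.t_reference(seg).channels)

    def test_norms_preserved(self, moving_segment):
        seg, truth = moving_segment
        out = tr.t_earth(seg, truth.quats)
        assert np.allclose(np.linalg.norm(out.channels[:3], axis=0),
                           np.linalg.norm(seg.acc, axis=1))

    def test_magnetometer_constant_in_earth_frame(self):
        spec = simulate.default_activity_specs()[7]
        acc, gyro, mag, truth = simulate.simulate_unit(spec, duration_s=5,
                                                       seed=2, noise=False)
        out = tr.t_earth(tr.UnitSegment(acc, gyro, mag), truth.quats)
        assert out.channels[6:9].std(axis=1).max() < 1e-9

    def test_length_mismatch_rejected(self, moving_segment):
        seg, truth = moving_segment
        with pytest.raises(ValueError):
            tr.t_earth(seg, truth.quats[:-1])


class TestDifferentialRotations:
    def test_constant_trajectory_gives_identity(self):
        quats = np.tile([1.0, 0, 0, 0], (50, 1))
        d = tr.differential_rotations(quats)
        assert np.allclose(d.matrices, np.eye(3))
        assert np.allclose(d.quaternions, [1, 0, 0, 0])
        assert d.quaternions.shape == (50, 4)

    def test_constant_earth_spin_closed_form(self):
        omega, dt = 1.3, 0.04
        t = np.arange(60) * dt
        quats = quat.quat_from_axis_angle(np.tile([0, 0, 1.0], (60, 1)), omega * t)
        d = tr.differential_rotations(quats)
        expected = quat.rotmat_from_quat(quat.quat_from_axis_angle([0, 0, 1],
                                                                   omega * dt))
        assert np.abs(d.matrices[:-1] - expected).max() < 1e-12

    def test_invariant_to_constant_reorientation(self, rng):
        # the similarity-transformed between-sample rotation is unchanged when
        # the trajectory is right-multiplied by any constant rotation
        for _ in range(50):
            q = quat.quat_normalize(rng.standard_normal((20, 4)))
            P = quat.random_rotation(rng)
            q_rot = quat.quat_from_rotmat(quat.rotmat_from_quat(q) @ P)
            d0 = tr.differential_rotations(q)
            d1 = tr.differential_rotations(q_rot)
            assert np.abs(d0.matrices - d1.matrices).max() < 1e-12

    def test_scalar_component_nonnegative(self, rng):
        q = quat.quat_normalize(rng.standard_normal((30, 4)))
        assert np.all(tr.differential_rotations(q).quaternions[:, 0] >= 0)


class TestProposed:
    def test_static_differential_channels(self):
        n = 125
        seg = tr.UnitSegment(np.tile([0, 0, 9.8], (n, 1)), np.zeros((n, 3)),
                             np.tile([0.5, 0, 0.8], (n, 1)))
        quats = np.tile([1.0, 0, 0, 0], (n, 1))
        out = tr.t_proposed(seg, quats)
        assert out.channels.shape == (13, n)
        assert np.allclose(out.channels[9], 1.0)    # qdiff scalar
        assert np.allclose(out.channels[10:], 0.0)  # qdiff vector

    def test_invariant_with_ground_truth_trajectories(self, moving_segment, rng):
        seg, truth = moving_segment
        P = quat.random_rotation(rng)
        q_rot = quat.quat_from_rotmat(quat.rotmat_from_quat(truth.quats) @ P.T)
        out = tr.t_proposed(seg, truth.quats)
        out_r = tr.t_proposed(_reoriented(seg, P), q_rot)
        assert np.abs(out.channels - out_r.channels).max() < 1e-9
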