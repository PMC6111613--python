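"""Synthetic multi-unit IMU data with ground-truth orientations.

The generator emulates the shape of a public daily/sports-activities
recording campaign: ``n_subjects`` x ``n_classes`` activities x 5-s segments,
five body-worn units, nine channels per unit (acc, gyro, mag), 25 Hz.  Each
activity is a :class:`MotionSpec`: a fixed body posture plus sinusoidal
angular velocity (body frame) and sinusoidal linear acceleration (Earth
frame).  Four activities are stationary postures with no motion, mirroring
the sitting/standing/lying group of the real campaign.

The emitted streams are consistent with the ground-truth orientation by
construction:

* the orientation trajectory integrates the specified body angular rate
  with fine sub-steps of the exact quaternion exponential,
* ``gyro`` is that body angular rate sampled at the output rate,
* ``acc = R^T (g_E + a_E)`` so a resting unit's acquired acceleration points
  Earth-down, and
* ``mag = R^T m_E`` with a fixed Earth-frame magnetic field (North plus a
  configurable dip component).

Three activity pairs differ only by swapping the x and y components of both
the angular-rate and the (horizontal) acceleration signatures; their
per-sample vector norms are identical, so norm-based pre-processing cannot
separate them while Earth-frame representations can.  Inter-subject
variability enters as per-subject amplitude and frequency scalings, and each
segment draws fresh oscillation phases and a small posture wobble.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .orientation import DEFAULT_MAG_DIP_DEG
from .quat import (quat_from_axis_angle, quat_multiply, quat_normalize,
                   quat_rotate, rotmat_from_quat)

DEFAULT_RATE = 25.0
DEFAULT_SEGMENT_SECONDS = 5.0
GRAVITY = 9.81

#: default sensor noise levels: acc m/s^2, gyro rad/s, mag relative
NOISE_ACC = 0.05
NOISE_GYRO = 0.005
NOISE_MAG_REL = 0.01

#: fixed posture offsets emulating placement on torso, both wrists, both knees
UNIT_POSTURES = (
    (0.0, 0.0, 0.0),
    (0.1, 1.2, 0.4),
    (-0.1, -1.2, -0.4),
    (1.0, 0.1, 2.2),
    (-1.0, -0.1, -2.2),
)


@dataclass
class MotionSpec:
    """One activity class: posture plus sinusoidal motion signature.

    ``gyro_amp``/``gyro_freq``/``gyro_phase`` parameterize the body-frame
    angular rate (rad/s, Hz, rad); ``acc_amp``/``acc_freq``/``acc_phase`` the
    Earth-frame linear acceleration (m/s^2, Hz, rad).  ``posture`` is the
    x/y/z Euler triple of the body orientation.  Stationary specs carry zero
    amplitudes.
    """

    name: str
    stationary: bool = False
    posture: tuple = (0.0, 0.0, 0.0)
    gyro_amp: tuple = (0.0, 0.0, 0.0)
    gyro_freq: tuple = (1.0, 1.0, 1.0)
    acc_amp: tuple = (0.0, 0.0, 0.0)
    acc_freq: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if min(self.gyro_amp) < 0 or min(self.acc_amp) < 0:
            raise ValueError("amplitudes must be non-negative")


def _swap_xy(spec: MotionSpec, name: str) -> MotionSpec:
    """Same signature with the x/y component tuples exchanged.

    The per-sample norms of every sensor stream are unchanged, which makes
    the pair indistinguishable to norm-based pre-processing.
    """
    sw = lambda t: (t[1], t[0], t[2])
    return replace(spec, name=name, gyro_amp=sw(spec.gyro_amp),
                   gyro_freq=sw(spec.gyro_freq), acc_amp=sw(spec.acc_amp),
                   acc_freq=sw(spec.acc_freq))


def default_activity_specs(n_classes: int = 19) -> list[MotionSpec]:
    """The default activity set: 4 stationary postures + 15 motion classes."""
    specs = [
        MotionSpec("sitting", stationary=True, posture=(0.5, 0.1, 0.3)),
        MotionSpec("standing", stationary=True, posture=(0.0, 0.0, 0.0)),
        MotionSpec("lying_back", stationary=True, posture=(np.pi / 2, 0.0, 0.1)),
        MotionSpec("lying_side", stationary=True, posture=(0.0, np.pi / 2, -0.2)),
    ]
    walk = MotionSpec("walk_a", posture=(0.0, 0.0, 0.0),
                      gyro_amp=(0.9, 0.3, 0.1), gyro_freq=(0.9, 1.8, 0.9),
                      acc_amp=(1.2, 0.3, 1.8), acc_freq=(0.9, 0.9, 1.8))
    climb = MotionSpec("climb_a", posture=(0.3, 0.0, 0.0),
                       gyro_amp=(1.1, 0.2, 0.4), gyro_freq=(0.6, 1.2, 0.6),
                       acc_amp=(1.5, 0.4, 2.2), acc_freq=(0.6, 0.6, 1.2))
    sway = MotionSpec("sway_a", posture=(0.0, 0.2, 0.0),
                      gyro_amp=(0.5, 1.2, 0.2), gyro_freq=(1.4, 0.7, 1.4),
                      acc_amp=(0.8, 1.6, 0.5), acc_freq=(0.7, 1.4, 0.7))
    specs += [walk, _swap_xy(walk, "walk_b"),
              climb, _swap_xy(climb, "climb_b"),
              sway, _swap_xy(sway, "sway_b")]
    # remaining classes: distinct frequency/amplitude/posture combinations
    base_freqs = (0.5, 0.8, 1.1, 1.5, 1.9, 2.3, 2.7, 3.1, 3.5)
    for i, f in enumerate(base_freqs):
        amp_g = 0.4 + 0.12 * i
        amp_a = 0.8 + 0.18 * i
        specs.append(MotionSpec(
            f"motion_{i}", posture=(0.15 * i, -0.1 * i, 0.25 * i),
            gyro_amp=(amp_g, 0.5 * amp_g, 0.25 * amp_g),
            gyro_freq=(f, 2.0 * f, f),
            acc_amp=(0.5 * amp_a, 0.3 * amp_a, amp_a),
            acc_freq=(f, f, 2.0 * f)))
    if n_classes > len(specs):
        raise ValueError(f"at most {len(specs)} default activity classes")
    return specs[:n_classes]


@dataclass
class GroundTruth:
    """Simulator-side truth: orientation, Earth-frame motion and references."""

    quats: np.ndarray        # (N, 4) unit quaternions, sensor -> Earth
    acc_earth: np.ndarray    # (N, 3) linear acceleration in the Earth frame
    gravity_earth: np.ndarray
    mag_earth: np.ndarray


@dataclass
class SyntheticDataset:
    """In-memory dataset: (segments, units, samples, 9) channel block.

    The last axis is acc x/y/z, gyro x/y/z, mag x/y/z.  ``quats`` carries the
    ground-truth orientation of every unit in every segment.
    """

    data: np.ndarray         # (S, U, N, 9)
    subjects: np.ndarray     # (S,) 0-based subject index
    activities: np.ndarray   # (S,) 0-based activity index
    segments: np.ndarray     # (S,) 0-based segment index within (subject, activity)
    quats: np.ndarray | None
    rate: float
    stationary: np.ndarray   # (K,) bool mask over activity classes
    class_names: list[str] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return self.data.shape[1]

    @property
    def n_classes(self) -> int:
        return self.stationary.shape[0]


# ---------------------------------------------------------------------------
# Core batched generator
# ---------------------------------------------------------------------------

def _integrate_batch(q0: np.ndarray, gyro_amp, gyro_freq, gyro_phase,
                     n_samples: int, rate: float, substeps: int = 6):
    """Integrate body-frame sinusoidal angular rates exactly per sub-step.

    Returns sampled quaternions (B, N, 4) and the angular rate at the sample
    instants (B, N, 3).
    """
    B = q0.shape[0]
    dt = 1.0 / rate
    dts = dt / substeps
    q = q0.copy()
    quats = np.empty((B, n_samples, 4))
    omega_fn = lambda t: gyro_amp * np.sin(2.0 * np.pi * gyro_freq * t + gyro_phase)
    gyro = np.empty((B, n_samples, 3))
    for n in range(n_samples):
        t_n = n * dt
        quats[:, n] = q
        gyro[:, n] = omega_fn(t_n)
        for s in range(substeps):
            om = omega_fn(t_n + (s + 0.5) * dts)
            angle = np.linalg.norm(om, axis=-1) * dts
            axis = np.where(angle[:, None] > 0.0, om, np.array([1.0, 0.0, 0.0]))
            q = quat_normalize(quat_multiply(q, quat_from_axis_angle(axis, angle)))
    return quats, gyro


def _emit_measurements(quats, gyro, acc_amp, acc_freq, acc_phase,
                       n_samples: int, rate: float, mag_dip_deg: float):
    t = np.arange(n_samples) / rate
    aE = acc_amp[:, None, :] * np.sin(
        2.0 * np.pi * acc_freq[:, None, :] * t[None, :, None]
        + acc_phase[:, None, :])
    d = np.radians(mag_dip_deg)
    mE = np.array([np.cos(d), 0.0, np.sin(d)])
    gE = np.array([0.0, 0.0, GRAVITY])
    R = rotmat_from_quat(quats)                     # (B, N, 3, 3)
    Rt = np.swapaxes(R, -1, -2)
    acc = np.einsum("bnij,bnj->bni", Rt, gE + aE)
    mag = np.einsum("bnij,j->bni", Rt, mE)
    return acc, mag, aE, gE, mE


def simulate_unit(spec: MotionSpec, duration_s: float = 5.0,
                  rate: float = DEFAULT_RATE, seed: int = 0,
                  unit_posture=(0.0, 0.0, 0.0), noise: bool = True,
                  mag_dip_deg: float = DEFAULT_MAG_DIP_DEG):
    """Simulate one sensor unit performing one activity.

    Returns ``(acc, gyro, mag, GroundTruth)`` with each stream ``(N, 3)``.
    The unit's orientation starts at the activity posture composed with the
    unit's placement posture and evolves with the body angular rate.
    """
    n = int(round(duration_s * rate))
    if n < 2:
        raise ValueError("duration x rate must give at least two samples")
    if max(spec.gyro_freq) >= rate / 2 or max(spec.acc_freq) >= rate / 2:
        raise ValueError("oscillation frequencies must be below the Nyquist rate")
    rng = np.random.default_rng(seed)
    from .quat import quat_from_rotmat, rotmat_from_euler
    q0 = quat_multiply(quat_from_rotmat(rotmat_from_euler(*spec.posture)),
                       quat_from_rotmat(rotmat_from_euler(*unit_posture)))[None]
    g_amp = np.asarray(spec.gyro_amp, float)[None]
    g_freq = np.asarray(spec.gyro_freq, float)[None]
    a_amp = np.asarray(spec.acc_amp, float)[None]
    a_freq = np.asarray(spec.acc_freq, float)[None]
    g_phase = rng.uniform(0.0, 2.0 * np.pi, (1, 3))
    a_phase = rng.uniform(0.0, 2.0 * np.pi, (1, 3))
    quats, gyro = _integrate_batch(q0, g_amp, g_freq, g_phase, n, rate)
    acc, mag, aE, gE, mE = _emit_measurements(quats, gyro, a_amp, a_freq,
                                              a_phase, n, rate, mag_dip_deg)
    if noise:
        acc = acc + rng.normal(0.0, NOISE_ACC, acc.shape)
        gyro = gyro + rng.normal(0.0, NOISE_GYRO, gyro.shape)
        mag = mag * (1.0 + rng.normal(0.0, NOISE_MAG_REL, mag.shape))
    truth = GroundTruth(quats[0], aE[0], gE, mE)
    return acc[0], gyro[0], mag[0], truth


def simulate_dataset(n_subjects: int = 8, n_classes: int = 19,
                     minutes: float = 5.0, rate: float = DEFAULT_RATE,
                     units: int = 5, seed: int = 0, noise: bool = True,
                     segment_s: float = DEFAULT_SEGMENT_SECONDS,
                     mag_dip_deg: float = DEFAULT_MAG_DIP_DEG,
                     specs: list[MotionSpec] | None = None) -> SyntheticDataset:
    """Generate a full synthetic dataset with ground-truth orientations.

    ``minutes`` of data per (subject, activity) are produced as independent
    ``segment_s``-second segments (default: 5 min -> 60 segments of 125
    samples at 25 Hz).  All randomness flows from ``seed``; a fixed seed
    regenerates the dataset bit for bit.
    """
    specs = specs or default_activity_specs(n_classes)
    if len(specs) != n_classes:
        raise ValueError("one MotionSpec per class required")
    n_seg = int(round(minutes * 60.0 / segment_s))
    n = int(round(segment_s * rate))
    for sp in specs:
        if max(sp.gyro_freq) >= rate / 2 or max(sp.acc_freq) >= rate / 2:
            raise ValueError(f"spec {sp.name!r} violates the Nyquist limit")
    rng = np.random.default_rng(seed)

    S = n_subjects * n_classes * n_seg
    B = S * units
    subjects = np.repeat(np.arange(n_subjects), n_classes * n_seg)
    activities = np.tile(np.repeat(np.arange(n_classes), n_seg), n_subjects)
    segments = np.tile(np.arange(n_seg), n_subjects * n_classes)

    # per-subject, per-class signature scalings (inter-subject variability)
    amp_scale = 1.0 + 0.08 * rng.standard_normal((n_subjects, n_classes))
    freq_scale = 1.0 + 0.04 * rng.standard_normal((n_subjects, n_classes))

    g_amp = np.array([sp.gyro_amp for sp in specs])[activities]
    g_freq = np.array([sp.gyro_freq for sp in specs])[activities]
    a_amp = np.array([sp.acc_amp for sp in specs])[activities]
    a_freq = np.array([sp.acc_freq for sp in specs])[activities]
    g_amp = g_amp * amp_scale[subjects, activities][:, None]
    a_amp = a_amp * amp_scale[subjects, activities][:, None]
    g_freq = g_freq * freq_scale[subjects, activities][:, None]
    a_freq = a_freq * freq_scale[subjects, activities][:, None]

    from .quat import quat_from_rotmat, rotmat_from_euler
    q_posture = np.stack([
        quat_from_rotmat(rotmat_from_euler(*sp.posture)) for sp in specs])
    q_unit = np.stack([
        quat_from_rotmat(rotmat_from_euler(*p)) for p in UNIT_POSTURES[:units]])

    # expand to (B = S * units): unit index varies fastest
    g_amp = np.repeat(g_amp, units, axis=0)
    g_freq = np.repeat(g_freq, units, axis=0)
    a_amp = np.repeat(a_amp, units, axis=0)
    a_freq = np.repeat(a_freq, units, axis=0)
    g_phase = rng.uniform(0.0, 2.0 * np.pi, (B, 3))
    a_phase = rng.uniform(0.0, 2.0 * np.pi, (B, 3))

    # initial orientation: activity posture (x) unit placement (x) small wobble
    wobble_axis = rng.standard_normal((B, 3))
    wobble_angle = rng.normal(0.0, np.radians(2.0), B)
    q_wob = quat_from_axis_angle(wobble_axis, wobble_angle)
    q0 = quat_multiply(
        quat_multiply(q_posture[np.repeat(activities, units)],
                      q_unit[np.tile(np.arange(units), S)]), q_wob)

    quats, gyro = _integrate_batch(q0, g_amp, g_freq, g_phase, n, rate)
    acc, mag, _, _, _ = _emit_measurements(quats, gyro, a_amp, a_freq,
                                           a_phase, n, rate, mag_dip_deg)
    if noise:
        acc = acc + rng.normal(0.0, NOISE_ACC, acc.shape)
        gyro = gyro + rng.normal(0.0, NOISE_GYRO, gyro.shape)
        mag = mag * (1.0 + rng.normal(0.0, NOISE_MAG_REL, mag.shape))

    data = np.concatenate([acc, gyro, mag], axis=-1).reshape(S, units, n, 9)
    quats = quats.reshape(S, units, n, 4)
    return SyntheticDataset(
        data=data, subjects=subjects, activities=activities, segments=segments,
        quats=quats, rate=rate,
        stationary=np.array([sp.stationary for sp in specs]),
        class_names=[sp.name for sp in specs])
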