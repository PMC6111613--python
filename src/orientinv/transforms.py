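"""The seven pre-processing transforms applied to one sensor unit's segment.

Each transform maps a :class:`UnitSegment` (tri-axial accelerometer,
gyroscope and magnetometer streams over one window) to a
:class:`TransformedSegment` whose channels feed the feature extractor:

=============  ========  ==========================================
technique      channels  orientation-invariant?
=============  ========  ==========================================
reference          9     no (assumes fixed unit orientation)
random             9     no (reference after a random re-orientation)
norm               3     yes, exactly
gravity            6     yes, exactly
svd                9     yes, exactly (after deterministic sign fixing)
earth              9     yes, up to orientation-estimation error
proposed          13     yes, up to orientation-estimation error
=============  ========  ==========================================

``earth`` rotates every sample into the Earth frame with the per-sample unit
orientation; ``proposed`` appends the four components of the differential
quaternion — the rotation of the unit between consecutive samples expressed
in the Earth frame via a similarity transformation — which is invariant to
the constant orientation at which the unit is worn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .quat import quat_from_rotmat, random_rotation, rotmat_from_quat

TECHNIQUES = ("reference", "random", "norm", "gravity", "svd", "earth", "proposed")

#: channels produced per sensor unit by each technique
CHANNELS_PER_UNIT = {
    "reference": 9, "random": 9, "norm": 3, "gravity": 6,
    "svd": 9, "earth": 9, "proposed": 13,
}

_SENSORS = ("acc", "gyro", "mag")
_AXES = ("x", "y", "z")


class DegenerateSegmentError(ValueError):
    """Raised when a transform's geometric construction is undefined."""


@dataclass
class UnitSegment:
    """One sensor unit's window: three (N, 3) streams at a fixed rate."""

    acc: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray
    rate: float = 25.0
    unit: int = 0

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.mag = np.asarray(self.mag, dtype=float)
        shapes = {a.shape for a in (self.acc, self.gyro, self.mag)}
        if len(shapes) != 1 or self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc, gyro, mag must share one (N, 3) shape")
        if not all(np.isfinite(a).all() for a in (self.acc, self.gyro, self.mag)):
            raise ValueError("segment contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    def streams(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.acc, self.gyro, self.mag


@dataclass
class TransformedSegment:
    """Named channel sequences (C, N) produced by one technique."""

    channels: np.ndarray
    names: list[str]
    technique: str

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.shape[0] != len(self.names):
            raise ValueError("one name per channel required")


@dataclass
class DifferentialRotationSeq:
    """Per-sample differential rotations D_n and their quaternions q_diff.

    Both sequences have the trajectory's full length; the final entry is a
    repeat of the last computed value so downstream channels stay length N.
    """

    matrices: np.ndarray   # (N, 3, 3)
    quaternions: np.ndarray  # (N, 4), scalar component >= 0


def _triaxial_names(prefix: str = "") -> list[str]:
    return [f"{prefix}{s}_{a}" for s in _SENSORS for a in _AXES]


# ---------------------------------------------------------------------------
# Techniques
# ---------------------------------------------------------------------------

def t_reference(seg: UnitSegment) -> TransformedSegment:
    """Identity pass-through: the nine raw axes, fixed-orientation baseline."""
    ch = np.concatenate([s.T for s in seg.streams()], axis=0)
    return TransformedSegment(ch, _triaxial_names(), "reference")


def t_random_rotation(seg: UnitSegment, rng) -> TransformedSegment:
    """Pre-multiply all three streams by one random rotation.

    Emulates the unit being worn at an arbitrary (but within-segment
    constant) orientation; deterministic for a fixed seed.
    """
    P = random_rotation(rng)
    ch = np.concatenate([(s @ P.T).T for s in seg.streams()], axis=0)
    return TransformedSegment(ch, _triaxial_names(), "random")


def t_norm(seg: UnitSegment) -> TransformedSegment:
    """Per-sample Euclidean norm of each sensor type (3 channels)."""
    ch = np.stack([np.linalg.norm(s, axis=1) for s in seg.streams()], axis=0)
    return TransformedSegment(ch, [f"{s}_norm" for s in _SENSORS], "norm")


def t_gravity(seg: UnitSegment, eps: float = 1e-8) -> TransformedSegment:
    """Signed amplitude along, and magnitude perpendicular to, gravity.

    The gravity direction is approximated by the normalized time-mean of the
    acceleration within the segment.  Both output channels per sensor type
    are invariant to any constant re-orientation of the unit because the
    estimated axis co-rotates with the data.
    """
    g = seg.acc.mean(axis=0)
    ng = np.linalg.norm(g)
    if ng < eps:
        raise DegenerateSegmentError("mean acceleration is (near) zero; "
                                     "gravity direction undefined")
    g_hat = g / ng
    rows, names = [], []
    for name, s in zip(_SENSORS, seg.streams()):
        along = s @ g_hat
        perp = np.linalg.norm(s - np.outer(along, g_hat), axis=1)
        rows += [along, perp]
        names += [f"{name}_along_g", f"{name}_perp_g"]
    return TransformedSegment(np.stack(rows, axis=0), names, "gravity")


def svd_axes(seg: UnitSegment) -> tuple[np.ndarray, np.ndarray]:
    """Principal axes of the unit's joint 3 x 3N data matrix.

    Returns the left singular vectors (columns, descending singular value)
    with a deterministic sign: each axis is flipped so that its
    largest-magnitude projection onto the data is positive, ties broken
    toward the earlier sample.  Degenerate (all-zero) data yield the
    identity axes with a warning.
    """
    M = np.concatenate([s.T for s in seg.streams()], axis=1)  # (3, 3N)
    if not np.any(M):
        warnings.warn("zero data matrix: falling back to identity axes")
        return np.eye(3), np.zeros(3)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    proj = U.T @ M
    idx = np.argmax(np.abs(proj), axis=1)          # first max -> earlier sample
    signs = np.sign(proj[np.arange(3), idx])
    signs[signs == 0.0] = 1.0
    return U * signs, s


def t_svd(seg: UnitSegment) -> TransformedSegment:
    """Re-express all three streams in the segment's principal axes."""
    U, _ = svd_axes(seg)
    ch = np.concatenate([(s @ U).T for s in seg.streams()], axis=0)
    names = [f"{s}_{p}" for s in _SENSORS for p in ("p1", "p2", "p3")]
    return TransformedSegment(ch, names, "svd")


def earth_frame(stream: np.ndarray, quats: np.ndarray) -> np.ndarray:
    """Rotate an (..., N, 3) stream into the Earth frame sample by sample."""
    R = rotmat_from_quat(quats)
    return np.einsum("...ij,...j->...i", R, stream)


def t_earth(seg: UnitSegment, quats: np.ndarray) -> TransformedSegment:
    """Sensor sequences with respect to the Earth frame (9 channels)."""
    quats = np.asarray(quats, dtype=float)
    if quats.shape != (seg.n_samples, 4):
        raise ValueError("orientation trajectory must be (N, 4) matching the segment")
    ch = np.concatenate([earth_frame(s, quats).T for s in seg.streams()], axis=0)
    return TransformedSegment(ch, [n + "_E" for n in _triaxial_names()], "earth")


def differential_quaternions(quats: np.ndarray) -> np.ndarray:
    """Differential quaternions of an (..., N, 4) trajectory, padded to length N.

    ``D_n = R_{n+1} R_n^T`` is the between-sample rotation expressed in the
    Earth frame; its quaternion has scalar component forced >= 0 and is close
    to (1, 0, 0, 0) for small inter-sample rotations.
    """
    R = rotmat_from_quat(quats)
    D = R[..., 1:, :, :] @ np.swapaxes(R[..., :-1, :, :], -1, -2)
    q = quat_from_rotmat(D)
    return np.concatenate([q, q[..., -1:, :]], axis=-2)


def differential_rotations(quats: np.ndarray) -> DifferentialRotationSeq:
    """Differential rotations of an (N, 4) trajectory.

    The sensor-frame between-sample rotation ``C_n = R_n^T R_{n+1}`` depends
    on how the unit is worn; its similarity transform into the Earth frame,
    ``D_n = R_n C_n R_n^T = R_{n+1} R_n^T``, does not.
    """
    quats = np.asarray(quats, dtype=float)
    if quats.ndim != 2 or quats.shape[0] < 2:
        raise ValueError("need an (N, 4) trajectory with N >= 2")
    R = rotmat_from_quat(quats)
    D = R[1:] @ np.swapaxes(R[:-1], -1, -2)
    D = np.concatenate([D, D[-1:]], axis=0)
    return DifferentialRotationSeq(D, quat_from_rotmat(D))


def t_proposed(seg: UnitSegment, quats: np.ndarray) -> TransformedSegment:
    """Earth-frame sensor sequences plus differential quaternions (13 channels)."""
    base = t_earth(seg, quats)
    dq = differential_quaternions(np.asarray(quats, dtype=float))
    ch = np.concatenate([base.channels, dq.T], axis=0)
    names = base.names + [f"qdiff_{i}" for i in range(1, 5)]
    return TransformedSegment(ch, names, "proposed")


def transform(seg: UnitSegment, technique: str, quats: np.ndarray | None = None,
              rng=None) -> TransformedSegment:
    """Apply a technique selected by name."""
    if technique not in TECHNIQUES:
        raise ValueError(f"unknown technique {technique!r}; choose from {TECHNIQUES}")
    if technique == "reference":
        return t_reference(seg)
    if technique == "random":
        return t_random_rotation(seg, rng)
    if technique == "norm":
        return t_norm(seg)
    if technique == "gravity":
        return t_gravity(seg)
    if technique == "svd":
        return t_svd(seg)
    if quats is None:
        raise ValueError(f"technique {technique!r} needs an orientation trajectory")
    if technique == "earth":
        return t_earth(seg, quats)
    return t_proposed(seg, quats)
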