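"""Per-sample sensor-unit orientation estimation from acc/gyro/mag streams.

The estimator fuses two sources of attitude information:

* a **short-term** estimate obtained by integrating the gyroscope angular
  rate with the first-order quaternion kinematic update, and
* a **long-term** estimate obtained by a Gauss-Newton solve that aligns the
  measured acceleration with the Earth-down axis and the horizontal part of
  the measured magnetic field with magnetic North.

The two are blended per sample by a normalized weighted average with weight
``mu`` toward the gyro estimate.  The Earth frame is North-East-Down: ``z``
points toward the Earth's centre, ``x`` toward the horizontal component of
the magnetic field.  The acquired acceleration of a unit at rest is assumed
to point Earth-down, and the simulator in :mod:`orientinv.simulate` emits
data under the identical convention.

Before filtering, a prefix of configurable duration (default 1 s) with zero
angular rate and the first sample's acc/mag held constant is prepended so
the filter reaches steady state before the data of interest; prefix outputs
are dropped.  The very first orientation is initialized algebraically from
the first acc/mag pair (TRIAD construction), so a static, reference-aligned
stream yields the identity orientation immediately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .quat import quat_from_rotmat, quat_multiply, quat_normalize, rotmat_from_quat

log = logging.getLogger(__name__)

#: magnetic dip (inclination) in degrees shared by the filter defaults and the
#: simulator, so both sides agree on the Earth-frame magnetic reference
DEFAULT_MAG_DIP_DEG = 55.0


@dataclass
class FilterConfig:
    """Tunable constants of the orientation filter.

    mu:
        fusion weight in (0, 1) toward the gyro-integrated estimate
        (mu -> 1: pure gyro integration; mu -> 0: pure accel/mag solution).
    gn_max_iter / gn_step_tol:
        Gauss-Newton iteration cap and early-exit threshold on the step norm.
    gravity:
        magnitude of gravity along Earth +z (down), m/s^2.
    mag_dip_deg:
        magnetic inclination; only the horizontal component of the field
        defines the North reference in the cost.
    prefix_seconds:
        duration of the constant prefix prepended before filtering.
    """

    mu: float = 0.95
    gn_max_iter: int = 10
    gn_step_tol: float = 1e-8
    gravity: float = 9.81
    mag_dip_deg: float = DEFAULT_MAG_DIP_DEG
    prefix_seconds: float = 1.0
    #: width (as a fraction of gravity) of the dynamic-motion down-weighting
    #: of the accelerometer residual; 0 disables the weighting
    acc_weight_scale: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 < self.mu < 1.0:
            raise ValueError("mu must lie in (0, 1)")
        if self.gn_max_iter < 1:
            raise ValueError("gn_max_iter must be >= 1")
        if self.prefix_seconds < 0.0:
            raise ValueError("prefix_seconds must be >= 0")

    @property
    def mag_reference(self) -> np.ndarray:
        d = np.radians(self.mag_dip_deg)
        return np.array([np.cos(d), 0.0, np.sin(d)])


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / np.where(n == 0.0, 1.0, n)


def _degenerate(a_hat: np.ndarray, m_hat: np.ndarray) -> np.ndarray:
    """True where acc and mag are (anti)parallel: heading is unobservable."""
    return np.linalg.norm(np.cross(a_hat, m_hat), axis=-1) < 1e-6


# ---------------------------------------------------------------------------
# Gyroscope integration
# ---------------------------------------------------------------------------

def integrate_gyro(q_prev, omega, dt: float) -> np.ndarray:
    """First-order quaternion kinematic update, normalized.

    ``q <- normalize(q + (dt/2) * q (x) (0, omega))`` with ``omega`` the
    body-frame angular rate in rad/s.  Broadcasts over leading axes.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    q_prev = np.asarray(q_prev, dtype=float)
    omega = np.asarray(omega, dtype=float)
    omega_q = np.concatenate([np.zeros(omega.shape[:-1] + (1,)), omega], axis=-1)
    return quat_normalize(q_prev + 0.5 * dt * quat_multiply(q_prev, omega_q))


# ---------------------------------------------------------------------------
# TRIAD initialization
# ---------------------------------------------------------------------------

def triad_init(acc, mag) -> np.ndarray:
    """Algebraic orientation from one acc/mag pair (batched).

    The Earth axes expressed in the sensor frame are taken as
    down = acc/|acc|, east = down x mag (normalized), north = east x down;
    the rows of the sensor->Earth rotation are exactly those vectors.
    Degenerate pairs fall back to the identity quaternion.
    """
    acc = np.atleast_2d(np.asarray(acc, dtype=float))
    mag = np.atleast_2d(np.asarray(mag, dtype=float))
    down = _unit(acc)
    m_hat = _unit(mag)
    east = np.cross(down, m_hat)
    bad = np.linalg.norm(east, axis=-1) < 1e-6
    east = _unit(np.where(bad[..., None], np.array([0.0, 1.0, 0.0]), east))
    north = np.cross(east, down)
    R = np.stack([north, east, down], axis=-2)
    q = quat_from_rotmat(R)
    q[bad] = np.array([1.0, 0.0, 0.0, 0.0])
    return q


# ---------------------------------------------------------------------------
# Gauss-Newton accel/mag correction
# ---------------------------------------------------------------------------

def _residual(q: np.ndarray, a_hat: np.ndarray, m_hat: np.ndarray) -> np.ndarray:
    """4-vector alignment residual [R(q) a_hat - z_down ; (R(q) m_hat)_East].

    The accelerometer rows vanish when the measured acceleration maps to the
    Earth-down axis; the magnetometer row is the East component of the
    rotated field, which vanishes exactly when its horizontal part points
    North.  Only the horizontal direction of the field enters the cost, so a
    mismatch between the true and assumed magnetic dip is not penalized.
    """
    R = rotmat_from_quat(q)
    aE = np.einsum("...ij,...j->...i", R, a_hat)
    mEy = np.einsum("...j,...j->...", R[..., 1, :], m_hat)
    r = np.concatenate([aE, mEy[..., None]], axis=-1)
    r[..., 2] -= 1.0  # gravity reference: unit z, Earth-down
    return r


def _gn_refine(q0: np.ndarray, acc: np.ndarray, mag: np.ndarray,
               config: FilterConfig) -> np.ndarray:
    """Batched Gauss-Newton descent on the accel/mag alignment cost.

    Runs up to ``gn_max_iter`` damped Gauss-Newton steps with step halving on
    cost increase, so the cost is non-increasing.  Elements whose acc and mag
    are (anti)parallel keep their initial value.  The accelerometer rows of
    the residual are down-weighted when the specific-force magnitude deviates
    from gravity (the gravity direction is unreliable during dynamic motion);
    a unit at rest keeps full weight.
    """
    acc = np.atleast_2d(acc)
    a_hat = _unit(acc)
    m_hat = _unit(np.atleast_2d(mag))
    q = np.atleast_2d(np.asarray(q0, dtype=float)).copy()
    frozen = _degenerate(a_hat, m_hat)
    eps = 1e-6
    eye4 = 1e-9 * np.eye(4)

    weight = np.ones(q.shape[:-1] + (4,))
    if config.acc_weight_scale > 0.0:
        dyn = np.abs(np.linalg.norm(acc, axis=-1) - config.gravity) / (
            config.acc_weight_scale * config.gravity)
        weight[..., :3] = np.exp(-dyn ** 2)[..., None]

    for _ in range(config.gn_max_iter):
        r = weight * _residual(q, a_hat, m_hat)
        cost = (r ** 2).sum(axis=-1)
        # numerical Jacobian wrt the four quaternion components
        J = np.empty(q.shape[:-1] + (4, 4))
        for k in range(4):
            dq = np.zeros(4)
            dq[k] = eps
            J[..., :, k] = (weight * _residual(quat_normalize(q + dq), a_hat,
                                               m_hat) - r) / eps
        g = np.einsum("...jk,...j->...k", J, r)
        H = np.einsum("...ji,...jk->...ik", J, J) + eye4
        delta = np.linalg.solve(H, g[..., None])[..., 0]

        # damped update: halve the step while the cost increases
        alpha = np.ones(q.shape[:-1] + (1,))
        q_new = q.copy()
        improved = np.zeros(q.shape[:-1], dtype=bool)
        for _half in range(5):
            trial = quat_normalize(q - alpha * delta)
            cost_trial = ((weight * _residual(trial, a_hat, m_hat)) ** 2).sum(axis=-1)
            better = (cost_trial <= cost) & ~improved
            q_new = np.where(better[..., None], trial, q_new)
            improved |= better
            if improved.all():
                break
            alpha = np.where(improved[..., None], alpha, alpha * 0.5)
        take = improved & ~frozen
        step = np.linalg.norm(np.where(take[..., None], q_new - q, 0.0), axis=-1)
        q = np.where(take[..., None], q_new, q)
        if step.max() < config.gn_step_tol:
            break
    return q


def gauss_newton_correction(q_init, acc, mag,
                            config: FilterConfig | None = None) -> np.ndarray:
    """Refine a single orientation from one acc/mag pair.

    Returns the unit quaternion that locally minimizes the alignment cost,
    starting from ``q_init``.  If acc and mag are (anti)parallel the
    orientation is unobservable and ``q_init`` is returned with a warning.
    """
    config = config or FilterConfig()
    acc = np.asarray(acc, dtype=float)
    mag = np.asarray(mag, dtype=float)
    if np.linalg.norm(acc) == 0.0 or np.linalg.norm(mag) == 0.0:
        raise ValueError("acc and mag must be non-zero vectors")
    if _degenerate(_unit(acc[None]), _unit(mag[None]))[0]:
        warnings.warn("acc and mag are parallel: orientation unobservable, "
                      "returning the initial estimate")
        return quat_normalize(np.asarray(q_init, dtype=float))
    q = _gn_refine(np.asarray(q_init, dtype=float)[None], acc[None], mag[None], config)
    return quat_normalize(q[0])


# ---------------------------------------------------------------------------
# Full filter
# ---------------------------------------------------------------------------

def estimate_orientation_batch(acc, gyro, mag, rate: float,
                               config: FilterConfig | None = None) -> np.ndarray:
    """Estimate orientation trajectories for a batch of streams.

    Parameters
    ----------
    acc, gyro, mag : (B, N, 3) arrays
        Sensor streams: acceleration (acquired vector points Earth-down at
        rest), angular rate in rad/s, magnetic field in any consistent unit.
    rate : float
        Sample rate in Hz.

    Returns
    -------
    (B, N, 4) array of unit quaternions (sensor -> Earth), one per sample.
    """
    config = config or FilterConfig()
    acc = np.asarray(acc, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    mag = np.asarray(mag, dtype=float)
    if acc.ndim != 3 or acc.shape[-1] != 3:
        raise ValueError("expected (B, N, 3) streams")
    if acc.shape[1] < 2:
        raise ValueError("need at least two samples")
    B, N, _ = acc.shape
    dt = 1.0 / float(rate)
    n_prefix = int(round(config.prefix_seconds * rate))

    q = triad_init(acc[:, 0], mag[:, 0])
    out = np.empty((B, N, 4))
    mu = config.mu
    zeros = np.zeros((B, 3))
    for n in range(-n_prefix, N):
        if n < 0:  # prefix: zero angular rate, first sample held constant
            a_n, g_n, m_n = acc[:, 0], zeros, mag[:, 0]
        else:
            a_n, g_n, m_n = acc[:, n], gyro[:, n], mag[:, n]
        if n > -n_prefix:
            # trapezoidal angular rate over the step reduces the phase lag of
            # the first-order update on oscillatory motion
            g_prev = gyro[:, n - 1] if n >= 1 else zeros
            q_gyro = integrate_gyro(q, 0.5 * (g_prev + g_n), dt)
        else:
            q_gyro = q
        q_gn = _gn_refine(q_gyro, a_n, m_n, config)
        # sign-align before averaging on the quaternion sphere
        sign = np.where((q_gyro * q_gn).sum(axis=-1, keepdims=True) < 0.0, -1.0, 1.0)
        q = quat_normalize(mu * q_gyro + (1.0 - mu) * sign * q_gn)
        if n >= 0:
            out[:, n] = q
    return out


def estimate_orientation(acc, gyro, mag, rate: float,
                         config: FilterConfig | None = None) -> np.ndarray:
    """Estimate the orientation trajectory of a single stream.

    ``acc``, ``gyro``, ``mag`` are ``(N, 3)`` arrays; returns ``(N, 4)`` unit
    quaternions describing the sensor frame with respect to the Earth frame
    at every sample.  See :func:`estimate_orientation_batch` for conventions.
    """
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 2:
        raise ValueError("expected (N, 3) streams; see estimate_orientation_batch")
    if acc.shape[0] < 2:
        raise ValueError("need at least two samples")
    out = estimate_orientation_batch(acc[None], np.asarray(gyro, float)[None],
                                     np.asarray(mag, float)[None], rate, config)
    return out[0]
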