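"""Rotation-matrix and unit-quaternion arithmetic.

Conventions used throughout the package
---------------------------------------
* Quaternions are **scalar-first** ``(q1, q2, q3, q4)`` with the Hamilton
  product.  A unit quaternion ``q`` and the rotation matrix ``R = rotmat_from_quat(q)``
  act on a column vector the same way: ``R @ v`` rotates ``v`` from the frame
  the quaternion describes into the frame it is described in (for sensor
  orientations: sensor frame -> Earth frame).
* Conversions force the scalar component to be non-negative, which removes the
  q / -q double-cover ambiguity from any time series of quaternions.
* Euler angles ``(theta, phi, psi)`` build the rotation as the left-to-right
  product of an x-rotation by ``theta``, a y-rotation by ``phi`` and a
  z-rotation by ``psi``.

All functions broadcast over leading axes, so a trajectory of N quaternions is
just an ``(N, 4)`` array.
"""

from __future__ import annotations

import numpy as np

#: tolerance used by the validity checks for orthonormality / unit norm
TOL = 1e-9


def _as_float(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} must be finite")
    return a


# ---------------------------------------------------------------------------
# Euler angles and random rotations
# ---------------------------------------------------------------------------

def rotmat_from_euler(theta: float, phi: float, psi: float) -> np.ndarray:
    """Rotation matrix ``Rx(theta) @ Ry(phi) @ Rz(psi)``.

    ``theta``, ``phi``, ``psi`` are the x, y and z rotation angles in radians.
    """
    t, p, s = (float(_as_float(a, "angle")) for a in (theta, phi, psi))
    ct, st = np.cos(t), np.sin(t)
    cp, sp = np.cos(p), np.sin(p)
    cs, ss = np.cos(s), np.sin(s)
    rx = np.array([[1.0, 0.0, 0.0], [0.0, ct, -st], [0.0, st, ct]])
    ry = np.array([[cp, 0.0, sp], [0.0, 1.0, 0.0], [-sp, 0.0, cp]])
    rz = np.array([[cs, -ss, 0.0], [ss, cs, 0.0], [0.0, 0.0, 1.0]])
    return rx @ ry @ rz


def random_euler(rng) -> np.ndarray:
    """Three independent angles uniform on ``[-pi, pi)``."""
    rng = np.random.default_rng(rng)
    return rng.uniform(-np.pi, np.pi, size=3)


def random_rotation(rng) -> np.ndarray:
    """Random rotation with independent x/y/z angles uniform on ``[-pi, pi)``.

    ``rng`` may be an integer seed or a ``numpy.random.Generator``; a fixed
    seed always yields the same matrix.
    """
    return rotmat_from_euler(*random_euler(rng))


# ---------------------------------------------------------------------------
# Quaternion <-> rotation matrix
# ---------------------------------------------------------------------------

def quat_from_rotmat(R) -> np.ndarray:
    """Convert rotation matrices ``(..., 3, 3)`` to unit quaternions ``(..., 4)``.

    The main branch is ``q1 = sqrt(1 + d11 + d22 + d33) / 2`` with the vector
    part ``(d32 - d23, d13 - d31, d21 - d12) / (4 q1)``.  When the trace is
    close to -1 (rotation angle near pi) that expression is ill-conditioned
    and the standard largest-diagonal branch is used instead.  The scalar
    component of the result is always >= 0.
    """
    R = _as_float(R, "rotation matrix")
    if R.shape[-2:] != (3, 3):
        raise ValueError("expected (..., 3, 3) rotation matrices")
    shape = R.shape[:-2]
    R = R.reshape(-1, 3, 3)
    n = R.shape[0]
    q = np.empty((n, 4))

    d11, d12, d13 = R[:, 0, 0], R[:, 0, 1], R[:, 0, 2]
    d21, d22, d23 = R[:, 1, 0], R[:, 1, 1], R[:, 1, 2]
    d31, d32, d33 = R[:, 2, 0], R[:, 2, 1], R[:, 2, 2]
    tr = d11 + d22 + d33

    main = tr > -1.0 + 1e-6
    if np.any(main):
        w = 0.5 * np.sqrt(1.0 + tr[main])
        q[main, 0] = w
        q[main, 1] = (d32[main] - d23[main]) / (4.0 * w)
        q[main, 2] = (d13[main] - d31[main]) / (4.0 * w)
        q[main, 3] = (d21[main] - d12[main]) / (4.0 * w)
    rest = ~main
    if np.any(rest):
        # largest-diagonal branches, applied element-wise
        for i in np.nonzero(rest)[0]:
            m = R[i]
            k = int(np.argmax(np.diag(m)))
            if k == 0:
                s = 2.0 * np.sqrt(max(1.0 + m[0, 0] - m[1, 1] - m[2, 2], 0.0))
                q[i] = [(m[2, 1] - m[1, 2]) / s, 0.25 * s,
                        (m[0, 1] + m[1, 0]) / s, (m[0, 2] + m[2, 0]) / s]
            elif k == 1:
                s = 2.0 * np.sqrt(max(1.0 - m[0, 0] + m[1, 1] - m[2, 2], 0.0))
                q[i] = [(m[0, 2] - m[2, 0]) / s, (m[0, 1] + m[1, 0]) / s,
                        0.25 * s, (m[1, 2] + m[2, 1]) / s]
            else:
                s = 2.0 * np.sqrt(max(1.0 - m[0, 0] - m[1, 1] + m[2, 2], 0.0))
                q[i] = [(m[1, 0] - m[0, 1]) / s, (m[0, 2] + m[2, 0]) / s,
                        (m[1, 2] + m[2, 1]) / s, 0.25 * s]

    q /= np.linalg.norm(q, axis=-1, keepdims=True)
    flip = q[:, 0] < 0.0
    q[flip] *= -1.0
    return q.reshape(shape + (4,))


def rotmat_from_quat(q) -> np.ndarray:
    """Convert quaternions ``(..., 4)`` to rotation matrices ``(..., 3, 3)``.

    Non-unit inputs are normalized first.  ``q`` and ``-q`` map to the same
    matrix.
    """
    q = _as_float(q, "quaternion")
    if q.shape[-1] != 4:
        raise ValueError("expected (..., 4) quaternions")
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n == 0.0):
        raise ValueError("cannot build a rotation from a zero quaternion")
    w, x, y, z = np.moveaxis(q / n, -1, 0)
    R = np.empty(q.shape[:-1] + (3, 3))
    R[..., 0, 0] = 1.0 - 2.0 * (y * y + z * z)
    R[..., 0, 1] = 2.0 * (x * y - w * z)
    R[..., 0, 2] = 2.0 * (x * z + w * y)
    R[..., 1, 0] = 2.0 * (x * y + w * z)
    R[..., 1, 1] = 1.0 - 2.0 * (x * x + z * z)
    R[..., 1, 2] = 2.0 * (y * z - w * x)
    R[..., 2, 0] = 2.0 * (x * z - w * y)
    R[..., 2, 1] = 2.0 * (y * z + w * x)
    R[..., 2, 2] = 1.0 - 2.0 * (x * x + y * y)
    return R


# ---------------------------------------------------------------------------
# Quaternion algebra
# ---------------------------------------------------------------------------

def quat_multiply(a, b) -> np.ndarray:
    """Hamilton product ``a (x) b`` (scalar-first), broadcasting over leading axes."""
    a = _as_float(a, "quaternion")
    b = _as_float(b, "quaternion")
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def quat_conjugate(a) -> np.ndarray:
    a = _as_float(a, "quaternion")
    return a * np.array([1.0, -1.0, -1.0, -1.0])


def quat_normalize(a) -> np.ndarray:
    a = _as_float(a, "quaternion")
    n = np.linalg.norm(a, axis=-1, keepdims=True)
    if np.any(n == 0.0):
        raise ValueError("cannot normalize a zero quaternion")
    return a / n


def quat_rotate(q, v) -> np.ndarray:
    """Rotate vectors ``v (..., 3)`` by quaternions ``q (..., 4)``.

    Equivalent to ``rotmat_from_quat(q) @ v`` but without forming matrices.
    """
    q = quat_normalize(q)
    w = q[..., :1]
    u = q[..., 1:]
    v = _as_float(v, "vector")
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def quat_from_axis_angle(axis, angle) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle`` radians about ``axis``."""
    axis = _as_float(axis, "axis")
    n = np.linalg.norm(axis, axis=-1, keepdims=True)
    if np.any(n == 0.0):
        raise ValueError("axis must be non-zero")
    angle = np.asarray(angle, dtype=float)[..., None]
    half = 0.5 * angle
    return np.concatenate([np.cos(half), np.sin(half) * axis / n], axis=-1)


def quat_angle_deg(a, b) -> np.ndarray:
    """Rotation angle (degrees) separating two unit quaternions."""
    a = quat_normalize(a)
    b = quat_normalize(b)
    dot = np.clip(np.abs((a * b).sum(axis=-1)), 0.0, 1.0)
    return np.degrees(2.0 * np.arccos(dot))


# ---------------------------------------------------------------------------
# Validity checks (used by tests and input validation)
# ---------------------------------------------------------------------------

def is_rotation_matrix(R, tol: float = TOL) -> bool:
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3):
        return False
    eye = np.eye(3)
    ortho = np.max(np.abs(np.swapaxes(R, -1, -2) @ R - eye))
    det = np.abs(np.linalg.det(R) - 1.0).max()
    return bool(ortho <= tol and det <= tol)
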