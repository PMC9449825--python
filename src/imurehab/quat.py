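"""Hamilton quaternion utilities (scalar-first, earth-to-sensor).

All quaternions are arrays of shape (..., 4) ordered (w, x, y, z).  A
quaternion ``q`` maps earth-frame coordinates into sensor-frame
coordinates through its standard rotation matrix: ``v_sensor = R(q) @
v_earth``.  Angular velocity is the vector part of ``2 * dq/dt ⊗ q*``,
which for a single-axis rotation of angle theta(t) equals ``dtheta/dt``
about that axis.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "multiply",
    "conjugate",
    "normalize",
    "from_axis_angle",
    "rotate",
    "to_matrix",
    "angular_velocity",
    "finite_difference_omega",
]


def multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product p ⊗ q, broadcasting over leading axes."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    pw, px, py, pz = np.moveaxis(p, -1, 0)
    qw, qx, qy, qz = np.moveaxis(q, -1, 0)
    return np.stack(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ],
        axis=-1,
    )


def conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("cannot normalize zero quaternion")
    return q / norm


def from_axis_angle(axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Unit quaternion(s) for rotation ``angle`` (rad) about unit ``axis``.

    ``angle`` may be an array; the axis is shared.  Returns (..., 4).
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    angle = np.asarray(angle, dtype=float)
    half = 0.5 * angle
    w = np.cos(half)
    s = np.sin(half)
    return np.stack(
        [w, s * axis[0], s * axis[1], s * axis[2]],
        axis=-1,
    )


def axis_angle_derivative(axis: np.ndarray, angle: np.ndarray, dangle_dt: np.ndarray) -> np.ndarray:
    """Time derivative of ``from_axis_angle(axis, angle(t))``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    half = 0.5 * np.asarray(angle, dtype=float)
    rate = 0.5 * np.asarray(dangle_dt, dtype=float)
    dw = -np.sin(half) * rate
    ds = np.cos(half) * rate
    return np.stack(
        [dw, ds * axis[0], ds * axis[1], ds * axis[2]],
        axis=-1,
    )


def to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices of shape (..., 3, 3) for unit quaternions."""
    w, x, y, z = np.moveaxis(np.asarray(q, dtype=float), -1, 0)
    m = np.empty(w.shape + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - z * w)
    m[..., 0, 2] = 2 * (x * z + y * w)
    m[..., 1, 0] = 2 * (x * y + z * w)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - x * w)
    m[..., 2, 0] = 2 * (x * z - y * w)
    m[..., 2, 1] = 2 * (y * z + x * w)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Apply q's rotation matrix to vector(s) v: earth -> sensor coords."""
    return np.einsum("...ij,...j->...i", to_matrix(q), np.asarray(v, dtype=float))


def angular_velocity(q: np.ndarray, qdot: np.ndarray) -> np.ndarray:
    """Vector part of 2 * qdot ⊗ q*  — rotation rate in rad/s."""
    return 2.0 * multiply(qdot, conjugate(q))[..., 1:]


def finite_difference_omega(q: np.ndarray, dt: float) -> np.ndarray:
    """Central-difference angular velocity of a sampled quaternion series.

    Independent of any analytic derivative: differentiates the sampled
    values directly (one-sided at the ends) and applies the same
    ``2 * qdot ⊗ q*`` map.
    """
    q = np.asarray(q, dtype=float)
    qdot = np.gradient(q, dt, axis=0)
    return angular_velocity(q, qdot)
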