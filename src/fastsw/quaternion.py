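"""Unit-quaternion geometry.

Conventions used throughout the package:

* component order is scalar-first, ``(w, x, y, z)``;
* a quaternion and its negation encode the same rotation (double cover), so
  all angular measures are sign-invariant;
* angles exposed by the API are in degrees, internal trigonometry in radians.

The angular deviation between two unit quaternions q0, q1 is the rotation
angle of the relative rotation, ``2 * arccos(|<q0, q1>|)``, with the absolute
dot product clamped to [0, 1] before the arccos so that rounding on
near-identical inputs cannot push it outside the domain.

``compose_counted`` and ``matrix_compose_counted`` evaluate rotation
composition with instrumented scalars (see :mod:`fastsw.counting`) to expose
the classic operation counts: 28 scalar operations for the Hamilton product
(16 multiplications, 12 additions/subtractions) versus 45 for the naive 3x3
matrix product (27 + 18).
"""

from __future__ import annotations

import numpy as np

from .counting import CountedFloat, OpCounter, counted
from .errors import InvalidOrientationError, NonUnitQuaternionError

__all__ = [
    "norm",
    "normalize",
    "is_unit",
    "angular_deviation",
    "slerp",
    "slerp_pairs",
    "hamilton",
    "quat_to_matrix",
    "align_signs",
    "compose_counted",
    "matrix_compose_counted",
]

#: Norm tolerance for the unit-quaternion contract on inputs.
UNIT_TOL = 1e-6

#: Below this value of sin(angle between the 4-vectors) SLERP falls back to
#: normalized linear interpolation; the geodesic and the chord are then
#: indistinguishable at double precision.
SLERP_SIN_CUTOFF = 1e-8


def norm(q) -> np.ndarray | float:
    """Euclidean norm of quaternion(s) with shape (..., 4)."""
    return np.linalg.norm(np.asarray(q, dtype=float), axis=-1)


def normalize(q) -> np.ndarray:
    """Scale quaternion(s) to unit norm, preserving direction.

    Raises :class:`InvalidOrientationError` for zero or non-finite input.
    """
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise InvalidOrientationError("quaternion has non-finite components")
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n == 0.0):
        raise InvalidOrientationError("zero-norm quaternion cannot be normalized")
    return q / n


def is_unit(q, tol: float = UNIT_TOL) -> bool:
    return bool(np.all(np.abs(norm(q) - 1.0) <= tol))


def _require_unit(q, name: str) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if not np.all(np.abs(np.linalg.norm(q, axis=-1) - 1.0) <= UNIT_TOL):
        raise NonUnitQuaternionError(f"{name} is not a unit quaternion (norm off by > {UNIT_TOL})")
    return q


def angular_deviation(q0, q1) -> np.ndarray | float:
    """Rotation angle in degrees between unit quaternions q0 and q1.

    Broadcasts over leading axes; returns values in [0, 180].  Sign-invariant:
    flipping either argument leaves the result unchanged.
    """
    q0 = _require_unit(q0, "q0")
    q1 = _require_unit(q1, "q1")
    dot = np.abs(np.sum(q0 * q1, axis=-1))
    dot = np.clip(dot, 0.0, 1.0)
    out = np.degrees(2.0 * np.arccos(dot))
    # bitwise-identical orientations are exactly zero apart: don't let the
    # dot product's last-bit rounding report a spurious ~1e-6 degree angle
    q0b, q1b = np.broadcast_arrays(q0, q1)
    same = np.all(q0b == q1b, axis=-1) | np.all(q0b == -q1b, axis=-1)
    return np.where(same, 0.0, out)[()]


def slerp(q0, q1, u):
    """Spherical linear interpolation between unit quaternions.

    Interpolates along the shortest arc (q1 is sign-flipped when the dot
    product is negative) with constant angular velocity in ``u``.  ``u`` may
    be a scalar or an array; the result has shape ``u.shape + (4,)``.
    """
    q0 = _require_unit(q0, "q0")
    q1 = _require_unit(q1, "q1")
    u = np.asarray(u, dtype=float)

    dot = float(np.dot(q0, q1))
    if dot < 0.0:
        q1 = -q1
        dot = -dot
    dot = min(dot, 1.0)
    theta = np.arccos(dot)
    sin_theta = np.sin(theta)

    uu = u[..., np.newaxis]
    if sin_theta < SLERP_SIN_CUTOFF:
        out = (1.0 - uu) * q0 + uu * q1
    else:
        out = (np.sin((1.0 - uu) * theta) * q0 + np.sin(uu * theta) * q1) / sin_theta
    # renormalize to keep |norm - 1| at rounding level regardless of path
    out = out / np.linalg.norm(out, axis=-1, keepdims=True)
    return out


def slerp_pairs(q0s: np.ndarray, q1s: np.ndarray, us: np.ndarray) -> np.ndarray:
    """Vectorized SLERP of paired rows: q0s[i] -> q1s[i] at fraction us[i].

    Used by reconstruction, where every query timestamp has its own bracketing
    pair of segment points.  Same geometry as :func:`slerp`.
    """
    q0s = np.asarray(q0s, dtype=float)
    q1s = np.asarray(q1s, dtype=float)
    us = np.asarray(us, dtype=float)

    dots = np.sum(q0s * q1s, axis=-1)
    sign = np.where(dots < 0.0, -1.0, 1.0)
    q1s = q1s * sign[:, None]
    dots = np.clip(np.abs(dots), 0.0, 1.0)

    theta = np.arccos(dots)
    sin_theta = np.sin(theta)
    small = sin_theta < SLERP_SIN_CUTOFF
    safe_sin = np.where(small, 1.0, sin_theta)

    w0 = np.where(small, 1.0 - us, np.sin((1.0 - us) * theta) / safe_sin)
    w1 = np.where(small, us, np.sin(us * theta) / safe_sin)
    out = w0[:, None] * q0s + w1[:, None] * q1s
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


def hamilton(a, b) -> np.ndarray:
    """Hamilton product a*b, scalar-first components."""
    aw, ax, ay, az = np.asarray(a, dtype=float)
    bw, bx, by, bz = np.asarray(b, dtype=float)
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def quat_to_matrix(q) -> np.ndarray:
    """Rotation matrix of a unit quaternion (scalar-first)."""
    w, x, y, z = _require_unit(q, "q")
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def align_signs(values: np.ndarray) -> np.ndarray:
    """Make a quaternion stream sign-continuous.

    Flips whole rows of an (m, 4) array so every consecutive pair has a
    non-negative dot product.  q and -q are the same rotation, but in
    component space a sign flip looks like a large jump, which would break
    any component-wise approximation; this removes that artefact.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected an (m, D) array of quaternion rows")
    dots = np.sum(values[:-1] * values[1:], axis=-1)
    flips = np.where(dots < 0.0, -1.0, 1.0)
    signs = np.concatenate([[1.0], np.cumprod(flips)])
    return values * signs[:, None]


def compose_counted(a, b) -> tuple[np.ndarray, int, int]:
    """Hamilton product with instrumented arithmetic.

    Returns ``(a*b, n_mul, n_addsub)``; the counts are (16, 12) for any
    operands — composition of two rotations costs 28 scalar operations in
    quaternion form.
    """
    c = OpCounter()
    aw, ax, ay, az = counted(np.asarray(a, dtype=float), c)
    bw, bx, by, bz = counted(np.asarray(b, dtype=float), c)
    w = aw * bw - ax * bx - ay * by - az * bz
    x = aw * bx + ax * bw + ay * bz - az * by
    y = aw * by - ax * bz + ay * bw + az * bx
    z = aw * bz + ax * by - ay * bx + az * bw
    out = np.array([float(w), float(x), float(y), float(z)])
    return out, c.mul, c.add


def matrix_compose_counted(A, B) -> tuple[np.ndarray, int, int]:
    """Naive 3x3 rotation-matrix product with instrumented arithmetic.

    Returns ``(A@B, n_mul, n_addsub)``; the counts are (27, 18) — 45 scalar
    operations, the cost quaternion composition undercuts.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != (3, 3) or B.shape != (3, 3):
        raise ValueError("expected 3x3 matrices")
    c = OpCounter()
    Ac = [[CountedFloat(A[i, j], c) for j in range(3)] for i in range(3)]
    Bc = [[CountedFloat(B[i, j], c) for j in range(3)] for i in range(3)]
    out = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            acc = Ac[i][0] * Bc[0][j]
            for k in range(1, 3):
                acc = acc + Ac[i][k] * Bc[k][j]
            out[i, j] = float(acc)
    return out, c.mul, c.add
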