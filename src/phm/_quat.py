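"""Minimal scalar-first quaternion algebra used by the generator and the
orientation filter.

Conventions (fixed package-wide): quaternions are ``(w, x, y, z)`` with the
scalar component first, unit norm, and represent body-to-world rotations.
Axes are right-handed.
"""

from __future__ import annotations

import numpy as np


def qmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a ⊗ b. Supports broadcasting over leading axes."""
    aw, ax, ay, az = np.moveaxis(np.asarray(a, float), -1, 0)
    bw, bx, by, bz = np.moveaxis(np.asarray(b, float), -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def qconj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def qnormalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, float)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def from_axis_angle(axis: np.ndarray, angle) -> np.ndarray:
    """Unit quaternion rotating by ``angle`` (rad) about ``axis``.

    ``angle`` may be an array; the result broadcasts with one quaternion per
    angle.
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    angle = np.asarray(angle, float)
    half = angle / 2.0
    s = np.sin(half)
    w = np.cos(half)
    v = s[..., None] * axis
    return np.concatenate([w[..., None], v], axis=-1)


def rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` from the body frame into the world frame."""
    v = np.asarray(v, float)
    qv = np.concatenate([np.zeros(v.shape[:-1] + (1,)), v], axis=-1)
    return qmul(qmul(q, qv), qconj(q))[..., 1:]


def rotate_inv(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` from the world frame into the body frame."""
    return rotate(qconj(q), v)


def angle_between(qa: np.ndarray, qb: np.ndarray) -> np.ndarray:
    """Rotation angle (rad) separating two unit quaternions (sign-agnostic)."""
    dot = np.abs(np.sum(np.asarray(qa) * np.asarray(qb), axis=-1))
    return 2.0 * np.arccos(np.clip(dot, -1.0, 1.0))


def enforce_sign_convention(q: np.ndarray) -> np.ndarray:
    """Scalar component ≥ 0 at the first sample, sign-continuity afterwards."""
    q = np.array(q, float, copy=True)
    if q.ndim == 1:
        return q if q[0] >= 0 else -q
    if q[0, 0] < 0:
        q[0] = -q[0]
    for i in range(1, len(q)):
        if np.dot(q[i], q[i - 1]) < 0:
            q[i] = -q[i]
    return q
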