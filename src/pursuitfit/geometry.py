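"""Planar pursuit geometry.

All motion is restricted to the horizontal plane, so angular quantities
(deviation angle, line-of-sight rates, turn rates) are represented by the
scalar z-component of the corresponding vertical vector. The sign convention
is counterclockwise-positive throughout: ``cross2(a, b) > 0`` when ``b`` lies
counterclockwise of ``a``.

Vectors are plain ``(..., 2)`` float arrays; every function broadcasts over
leading dimensions.
"""

from __future__ import annotations

import numpy as np


class GeometryError(ValueError):
    """Raised when a geometric quantity is undefined (zero-length vector)."""


def cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Scalar (z-component) cross product of planar vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def rotate90(v: np.ndarray) -> np.ndarray:
    """Rotate a planar vector by +90 degrees (counterclockwise).

    Multiplying a scalar angular rate by ``rotate90(v)`` is the planar
    equivalent of crossing a vertical angular-rate vector with ``v``.
    """
    v = np.asarray(v, dtype=float)
    return np.stack([-v[..., 1], v[..., 0]], axis=-1)


def _norm(v: np.ndarray) -> np.ndarray:
    return np.hypot(v[..., 0], v[..., 1])


def signed_deviation_angle(r: np.ndarray, v_p: np.ndarray) -> np.ndarray:
    """Signed deviation angle between the line-of-sight and pursuer velocity.

    Parameters
    ----------
    r : (..., 2) array
        Line-of-sight vector (target position minus pursuer position, m).
    v_p : (..., 2) array
        Pursuer velocity (m/s).

    Returns
    -------
    Signed angle in radians in (-pi, pi]: the magnitude equals
    ``arccos(r . v_p / (|r| |v_p|))`` and the sign is positive when ``v_p``
    lies counterclockwise of ``r``.

    Raises
    ------
    GeometryError
        If either vector has zero length.
    """
    r = np.asarray(r, dtype=float)
    v_p = np.asarray(v_p, dtype=float)
    if np.any(_norm(r) == 0.0):
        raise GeometryError("deviation angle undefined: zero-length line-of-sight")
    if np.any(_norm(v_p) == 0.0):
        raise GeometryError("deviation angle undefined: zero pursuer velocity")
    return np.arctan2(cross2(r, v_p), np.sum(r * v_p, axis=-1))


def inertial_los_rate(r: np.ndarray, v_t: np.ndarray, v_p: np.ndarray) -> np.ndarray:
    """Inertial line-of-sight rate (rad/s), counterclockwise-positive.

    The angular rate of the line-of-sight measured in a fixed frame:
    ``cross(r, v_t - v_p) / |r|^2``. It reflects the relative motion of
    target and pursuer across the line-of-sight.
    """
    r = np.asarray(r, dtype=float)
    v_t = np.asarray(v_t, dtype=float)
    v_p = np.asarray(v_p, dtype=float)
    r2 = np.sum(r * r, axis=-1)
    if np.any(r2 == 0.0):
        raise GeometryError("line-of-sight rate undefined: coincident positions")
    return cross2(r, v_t - v_p) / r2


def background_los_rate(r: np.ndarray, v_t: np.ndarray) -> np.ndarray:
    """Background line-of-sight rate (rad/s), counterclockwise-positive.

    The angular rate of the line-of-sight measured against a visual
    background lying immediately behind the target: ``cross(r, v_t) / |r|^2``.
    It depends only on the target's own motion, so it carries no information
    about the pursuer's self-motion.
    """
    r = np.asarray(r, dtype=float)
    v_t = np.asarray(v_t, dtype=float)
    r2 = np.sum(r * r, axis=-1)
    if np.any(r2 == 0.0):
        raise GeometryError("line-of-sight rate undefined: coincident positions")
    return cross2(r, v_t) / r2
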