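"""Planar circular geometry shared by the game world and the agent models.

Angles are radians in [0, 2*pi); positions are 2-vectors in an abstract plane
with the actor-screen centre at the origin and y pointing up.
"""

from __future__ import annotations

import math

import numpy as np

TWO_PI = 2.0 * math.pi


class DegenerateStimulusError(ValueError):
    """Raised when a target-difference angle is requested for a zero vector.

    A cursor sitting exactly on its target carries no directional stimulus;
    callers must treat this as "goal reached" rather than query an angle.
    """


def wrap_angle(angle: float) -> float:
    """Map an angle onto [0, 2*pi)."""
    return angle % TWO_PI


def angle_to_unit(angle: float) -> np.ndarray:
    """Unit vector with the given polar angle (the paper's phi map)."""
    if not math.isfinite(angle):
        raise ValueError(f"angle must be finite, got {angle!r}")
    return np.array([math.cos(angle), math.sin(angle)])


def vector_angle(vec) -> float:
    """Polar angle of a non-zero 2-vector, in [0, 2*pi)."""
    x, y = float(vec[0]), float(vec[1])
    if x == 0.0 and y == 0.0:
        raise DegenerateStimulusError("zero vector has no direction")
    return math.atan2(y, x) % TWO_PI


def target_difference_angle(cursor, target) -> float:
    """Angle psi of the target-difference vector (target - cursor).

    This is the stimulus convention used throughout the package: the
    stimulus points *at* the goal.
    """
    dx = float(target[0]) - float(cursor[0])
    dy = float(target[1]) - float(cursor[1])
    if dx == 0.0 and dy == 0.0:
        raise DegenerateStimulusError("cursor coincides with target")
    return math.atan2(dy, dx) % TWO_PI


def circular_distance(a: float, b: float) -> float:
    """Angular distance between two angles, in [0, pi]."""
    d = (a - b) % TWO_PI
    return min(d, TWO_PI - d)


def circular_distance_array(a, b):
    """Vectorised :func:`circular_distance`."""
    d = np.asarray(a - b) % TWO_PI
    return np.minimum(d, TWO_PI - d)


def circular_mean_resultant(angles, weights=None):
    """Resultant length R in [0, 1] and mean angle of a set of angles.

    Returns ``(R, theta)``; ``theta`` is ``nan`` when R is (numerically) zero.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        return 0.0, float("nan")
    c = np.cos(angles)
    s = np.sin(angles)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        tot = w.sum()
        if tot <= 0:
            return 0.0, float("nan")
        mx, my = (w * c).sum() / tot, (w * s).sum() / tot
    else:
        mx, my = c.mean(), s.mean()
    r = math.hypot(mx, my)
    if r < 1e-12:
        return r, float("nan")
    return r, math.atan2(my, mx) % TWO_PI
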