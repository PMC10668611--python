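"""Small planar-geometry helpers shared by the simulator and the metrics.

All functions operate in physical (micron) coordinates: x increases
temporal-to-nasal, y increases with depth. Angles are in degrees; a
positive angle tilts a downward-pointing vector toward the nasal side.
"""

from __future__ import annotations

import numpy as np

from .core import InvalidParameterError, NonIntersectingRayError


def rotate_toward_nasal(v: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate a 2-D vector; positive angles tilt a downward vector toward +x."""
    th = np.deg2rad(degrees)
    c, s = np.cos(th), np.sin(th)
    v = np.asarray(v, dtype=float)
    return np.array([c * v[0] + s * v[1], -s * v[0] + c * v[1]])


def signed_angle_deg(direction: np.ndarray, normal: np.ndarray) -> float:
    """Signed angle from ``normal`` to ``direction``, positive toward nasal."""
    d = np.asarray(direction, dtype=float)
    n = np.asarray(normal, dtype=float)
    if np.hypot(*d) == 0 or np.hypot(*n) == 0:
        raise InvalidParameterError("zero-length vector has no direction")
    cross = d[0] * n[1] - d[1] * n[0]
    dot = d[0] * n[0] + d[1] * n[1]
    return float(np.degrees(np.arctan2(cross, dot)))


def tangent_and_inward_normal(
    xs: np.ndarray, ys: np.ndarray, x0: float, half_window: float
) -> tuple[np.ndarray, np.ndarray]:
    """Local least-squares tangent of a sampled curve and its downward normal.

    Fits a straight line to the curve points with ``|x - x0| <= half_window``
    and returns unit (tangent, inward normal); the normal has positive y
    (points from the upper boundary down into the choroid).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    mask = np.abs(xs - x0) <= half_window
    if mask.sum() < 2:
        # widen to the two nearest samples
        order = np.argsort(np.abs(xs - x0))
        mask = np.zeros_like(mask)
        mask[order[:2]] = True
    slope = np.polyfit(xs[mask], ys[mask], 1)[0]
    tangent = np.array([1.0, slope])
    tangent /= np.hypot(*tangent)
    normal = np.array([-tangent[1], tangent[0]])
    if normal[1] < 0:
        normal = -normal
    return tangent, normal


def ray_polyline_distance(
    origin: np.ndarray,
    direction: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
) -> float:
    """Distance along a ray to its first crossing of a piecewise-linear curve.

    Raises :class:`NonIntersectingRayError` when the ray never meets the
    polyline within its x-extent.
    """
    ox, oy = float(origin[0]), float(origin[1])
    dx, dy = float(direction[0]), float(direction[1])
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    x0, y0 = xs[:-1], ys[:-1]
    ex, ey = xs[1:] - x0, ys[1:] - y0
    denom = dx * ey - dy * ex
    with np.errstate(divide="ignore", invalid="ignore"):
        t = ((x0 - ox) * ey - (y0 - oy) * ex) / denom
        u = ((x0 - ox) * dy - (y0 - oy) * dx) / denom
    ok = (np.abs(denom) > 1e-12) & (t > 1e-9) & (u >= -1e-9) & (u <= 1 + 1e-9)
    if not np.any(ok):
        raise NonIntersectingRayError(
            "measurement ray does not intersect the target boundary"
        )
    return float(t[ok].min())
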