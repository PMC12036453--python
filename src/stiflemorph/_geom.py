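"""Small shared planar-geometry helpers."""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError


def shoelace_area(poly: np.ndarray) -> float:
    """Signed-magnitude area of a closed polygon given as ordered (n, 2) vertices."""
    p = np.asarray(poly, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def convex_hull_area(points: np.ndarray) -> float:
    """Area of the 2D convex hull of a point set.

    Raises :class:`scipy.spatial.QhullError` for < 3 points or collinear input;
    callers decide whether that becomes a missing value or a hard error.
    """
    pts = np.asarray(points, dtype=float)
    hull = ConvexHull(pts)
    return shoelace_area(pts[hull.vertices])


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit direction ``a`` onto unit direction ``b``."""
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis orthogonal to a
        ortho = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            ortho = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, ortho)
        return rotation_about_axis(axis, np.pi)
    angle = np.arctan2(np.linalg.norm(v), c)
    return rotation_about_axis(v, angle)


__all__ = [
    "shoelace_area",
    "convex_hull_area",
    "rotation_about_axis",
    "rotation_aligning",
    "QhullError",
]
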