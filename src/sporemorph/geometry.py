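"""Small planar-geometry helpers shared across the package.

A polygon is a float array of shape (N, 2) holding ordered (x, y)
vertices in micrometres, y-axis pointing up. Closure is implicit
(the last vertex is not a repeat of the first). The package-wide
convention is counterclockwise orientation, i.e. positive signed area.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import directed_hausdorff

__all__ = [
    "signed_area",
    "centroid",
    "perimeter",
    "ensure_ccw",
    "hausdorff",
    "resample_closed",
    "turning_angles",
]


def as_polygon(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("polygon must be an (N>=3, 2) array of vertices")
    if not np.all(np.isfinite(pts)):
        raise ValueError("polygon contains non-finite coordinates")
    return pts


def signed_area(poly: np.ndarray) -> float:
    """Shoelace signed area; positive for counterclockwise vertex order."""
    p = np.asarray(poly, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def centroid(poly: np.ndarray) -> np.ndarray:
    """Vertex-mean centroid (adequate for densely sampled outlines)."""
    return np.asarray(poly, dtype=float).mean(axis=0)


def perimeter(poly: np.ndarray) -> float:
    p = np.asarray(poly, dtype=float)
    d = np.diff(np.vstack([p, p[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def ensure_ccw(poly: np.ndarray) -> np.ndarray:
    """Return the polygon in counterclockwise order, keeping the first vertex."""
    p = as_polygon(poly)
    if signed_area(p) < 0:
        p = np.vstack([p[:1], p[1:][::-1]])
    return p


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets."""
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


def resample_closed(poly: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed polygon to ``n_points`` equally spaced in arc length."""
    p = as_polygon(poly)
    closed = np.vstack([p, p[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("zero-perimeter polygon")
    target = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return np.column_stack([x, y])


def turning_angles(poly: np.ndarray) -> np.ndarray:
    """Unsigned exterior (turning) angle at every vertex of a closed polygon."""
    p = as_polygon(poly)
    e = np.diff(np.vstack([p, p[:1]]), axis=0)  # edge i: p[i] -> p[i+1]
    prev = np.roll(e, 1, axis=0)
    cross = prev[:, 0] * e[:, 1] - prev[:, 1] * e[:, 0]
    dot = (prev * e).sum(axis=1)
    return np.abs(np.arctan2(cross, dot))
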