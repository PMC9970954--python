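"""Reference shapes for the Draw a Shape Test.

The test presents six pre-written shapes of increasing complexity: two
diagonal lines, a square, a circle, a figure-of-8, and a spiral.  Each is
represented here as an ordered polyline of waypoints on an abstract
600×600 px canvas; trace accuracy is defined as waypoint coverage against
these polylines.  Angular and radial drawing velocities are only meaningful
for the round shapes (circle, figure-of-8, spiral), which wind around their
centroid.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

SHAPE_IDS = ("line1", "line2", "square", "circle", "figure8", "spiral")
ROUND_SHAPES = frozenset({"circle", "figure8", "spiral"})

_CX, _CY = 300.0, 300.0


@lru_cache(maxsize=None)
def waypoints(shape: str) -> np.ndarray:
    """Reference waypoints of ``shape`` as an (n, 2) array of px coordinates."""
    if shape == "line1":
        t = np.linspace(0.0, 1.0, 16)
        pts = np.column_stack([100 + 400 * t, 100 + 400 * t])
    elif shape == "line2":
        t = np.linspace(0.0, 1.0, 16)
        pts = np.column_stack([500 - 400 * t, 100 + 400 * t])
    elif shape == "square":
        s = np.linspace(0.0, 1.0, 9)[:-1]  # 8 points per side
        lo, hi = 150.0, 450.0
        top = np.column_stack([lo + (hi - lo) * s, np.full_like(s, lo)])
        right = np.column_stack([np.full_like(s, hi), lo + (hi - lo) * s])
        bottom = np.column_stack([hi - (hi - lo) * s, np.full_like(s, hi)])
        left = np.column_stack([np.full_like(s, lo), hi - (hi - lo) * s])
        pts = np.vstack([top, right, bottom, left, [[lo, lo]]])
    elif shape == "circle":
        th = np.linspace(0.0, 2 * np.pi, 49)
        pts = np.column_stack([_CX + 180 * np.cos(th), _CY + 180 * np.sin(th)])
    elif shape == "figure8":
        t = np.linspace(0.0, 2 * np.pi, 65)
        pts = np.column_stack([_CX + 200 * np.sin(t),
                               _CY + 190 * np.sin(t) * np.cos(t)])
    elif shape == "spiral":
        th = np.linspace(0.0, 4 * np.pi, 97)
        r = 20.0 + (170.0 - 20.0) * th / (4 * np.pi)
        pts = np.column_stack([_CX + r * np.cos(th), _CY + r * np.sin(th)])
    else:
        raise ValueError(f"unknown shape id {shape!r}")
    return pts


def centroid(shape: str) -> np.ndarray:
    """Centroid of the reference waypoints (rotation centre for round shapes)."""
    return waypoints(shape).mean(axis=0)


def tolerance_radius(shape: str, fraction: float = 0.05) -> float:
    """Waypoint-coverage tolerance: ``fraction`` of the bounding-box diagonal."""
    pts = waypoints(shape)
    span = pts.max(axis=0) - pts.min(axis=0)
    return float(fraction * np.hypot(*span))


def path_length(shape: str) -> float:
    """Total arc length of the reference polyline, px."""
    pts = waypoints(shape)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def resample_arclength(shape: str, n: int) -> np.ndarray:
    """Resample the reference polyline at ``n`` equal-arc-length positions."""
    pts = waypoints(shape)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, s[-1], n)
    xs = np.interp(target, s, pts[:, 0])
    ys = np.interp(target, s, pts[:, 1])
    return np.column_stack([xs, ys])
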