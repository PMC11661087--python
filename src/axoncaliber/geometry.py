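"""Polyline centerline utilities: arc-length parameterization, tangents, normals.

Centerlines are ordered 2D point lists in micrometers.  All downstream
measurement is expressed in arc length ``s`` along the polyline, so the
helpers here are the single place where the discrete polyline is turned
into a continuous curve.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "polyline_arclength",
    "polyline_length",
    "point_at",
    "tangent_and_normal",
    "resample_polyline",
    "DegenerateSegmentError",
]


class DegenerateSegmentError(ValueError):
    """Raised when a centerline has fewer than two distinct points."""


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (N, 2) point array, got shape {pts.shape}")
    return pts


def polyline_arclength(points) -> np.ndarray:
    """Cumulative arc length at each vertex, starting at 0."""
    pts = _as_points(points)
    if len(pts) < 2:
        raise DegenerateSegmentError("centerline needs at least two points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise DegenerateSegmentError("centerline has zero total length")
    return s


def polyline_length(points) -> float:
    return float(polyline_arclength(points)[-1])


def point_at(points, s: float) -> np.ndarray:
    """Point on the polyline at arc position ``s`` (linear interpolation)."""
    pts = _as_points(points)
    cum = polyline_arclength(pts)
    s = float(np.clip(s, 0.0, cum[-1]))
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    return np.array([x, y])


def _vertex_tangents(pts: np.ndarray) -> np.ndarray:
    # central differences at interior vertices, one-sided at the ends
    t = np.empty_like(pts)
    t[0] = pts[1] - pts[0]
    t[-1] = pts[-1] - pts[-2]
    if len(pts) > 2:
        t[1:-1] = pts[2:] - pts[:-2]
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise DegenerateSegmentError("repeated points give a zero tangent")
    return t / norms


def tangent_and_normal(points, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit tangent and unit normal of the centerline at arc position ``s``.

    The tangent comes from central differences on the polyline vertices
    (one-sided at the ends), interpolated along arc length; the normal is
    the tangent rotated by +90 degrees.
    """
    pts = _as_points(points)
    cum = polyline_arclength(pts)
    if not (-1e-9 <= s <= cum[-1] + 1e-9):
        raise ValueError(f"s={s} outside [0, {cum[-1]:.4f}]")
    vt = _vertex_tangents(pts)
    s = float(np.clip(s, 0.0, cum[-1]))
    tx = np.interp(s, cum, vt[:, 0])
    ty = np.interp(s, cum, vt[:, 1])
    t = np.array([tx, ty])
    t /= np.linalg.norm(t)
    n = np.array([-t[1], t[0]])
    return t, n


def resample_polyline(points, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample at (approximately) uniform arc-length spacing.

    Returns ``(s_values, points)`` where the spacing is the largest value
    <= ``step`` that divides the total length evenly, so the endpoints are
    always included.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    pts = _as_points(points)
    cum = polyline_arclength(pts)
    total = cum[-1]
    n = max(int(np.ceil(total / step)), 1)
    s = np.linspace(0.0, total, n + 1)
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    return s, np.column_stack([x, y])
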