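"""Primitives for closed lesion outlines.

An outline is an ``(n, 2)`` float array of ``(x, y)`` vertices of a simple
closed polygon, stored cyclically (the first vertex is *not* repeated at the
end). Functions here are deliberately dumb geometry: resampling, orientation,
centroid size, and radial ray-casting used by the asymmetry index.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon


def as_outline(points) -> np.ndarray:
    """Coerce to an (n, 2) float outline, dropping a duplicated endpoint."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("outline must be an (n, 2) array")
    if pts.shape[0] >= 2 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if pts.shape[0] < 3:
        raise ValueError("outline needs at least 3 distinct points")
    return pts


def centroid(outline: np.ndarray) -> np.ndarray:
    return np.asarray(outline, dtype=float).mean(axis=0)


def centroid_size(outline: np.ndarray) -> float:
    """Root of the summed squared vertex-to-centroid distances.

    The standard morphometric centroid size; for a unit circle sampled at
    m points this is sqrt(m).
    """
    pts = as_outline(outline)
    d2 = ((pts - pts.mean(axis=0)) ** 2).sum(axis=1)
    return float(np.sqrt(d2.sum()))


def signed_area(outline: np.ndarray) -> float:
    pts = np.asarray(outline, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def ensure_ccw(outline: np.ndarray) -> np.ndarray:
    """Return the outline oriented counter-clockwise (positive signed area)."""
    pts = as_outline(outline)
    return pts if signed_area(pts) > 0 else pts[::-1].copy()


def is_simple(outline: np.ndarray) -> bool:
    """True when the closed polygon does not self-intersect."""
    pts = as_outline(outline)
    return bool(Polygon(pts).is_valid)


def perimeter(outline: np.ndarray) -> float:
    pts = as_outline(outline)
    seg = np.roll(pts, -1, axis=0) - pts
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def cumulative_arclength(outline: np.ndarray) -> np.ndarray:
    """Cumulative chord length at each vertex, starting at 0; length n+1
    (the last entry is the full perimeter, closing the loop)."""
    pts = as_outline(outline)
    seg = np.roll(pts, -1, axis=0) - pts
    steps = np.hypot(seg[:, 0], seg[:, 1])
    return np.concatenate([[0.0], np.cumsum(steps)])


def resample_by_arclength(outline: np.ndarray, n_points: int) -> np.ndarray:
    """Resample the closed polyline at ``n_points`` equal arc-length steps,
    keeping the current first vertex as the first sample."""
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    pts = as_outline(outline)
    closed = np.vstack([pts, pts[:1]])
    t = cumulative_arclength(pts)
    total = t[-1]
    if total <= 0:
        raise ValueError("degenerate outline with zero perimeter")
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(targets, t, closed[:, 0])
    y = np.interp(targets, t, closed[:, 1])
    return np.column_stack([x, y])


def roll_to_start(outline: np.ndarray) -> np.ndarray:
    """Cyclically shift so the vertex of maximum x (tie: maximum y) is first."""
    pts = as_outline(outline)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    return np.roll(pts, -int(order[-1]), axis=0)


def radial_profile(outline: np.ndarray, n_rays: int, center=None) -> np.ndarray:
    """Radius of the outline along ``n_rays`` equally spaced rays from the
    centroid (angles 2*pi*j/n_rays). For non-star-shaped outlines the
    outermost boundary intersection is used.

    Implemented as a vectorised ray/segment intersection over all polygon
    edges, so it needs no star-shape assumption.
    """
    pts = as_outline(outline)
    c = centroid(pts) if center is None else np.asarray(center, dtype=float)
    p = pts - c
    q = np.roll(p, -1, axis=0)  # segment endpoints p_i -> q_i
    theta = 2.0 * np.pi * np.arange(n_rays) / n_rays
    d = np.column_stack([np.cos(theta), np.sin(theta)])  # (m, 2) ray dirs

    # Solve  s*d_j = p_i + u*(q_i - p_i)  for each ray j, segment i.
    e = q - p  # (n, 2)
    # Cross products via broadcasting: denom[j, i] = d_j x e_i
    denom = d[:, 0, None] * e[None, :, 1] - d[:, 1, None] * e[None, :, 0]
    num_u = d[:, 0, None] * p[None, :, 1] - d[:, 1, None] * p[None, :, 0]
    num_s = p[None, :, 0] * e[None, :, 1] - p[None, :, 1] * e[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = -num_u / denom
        s = -num_s / denom
    hit = (denom != 0) & (u >= -1e-12) & (u <= 1.0 + 1e-12) & (s > 0)
    s = np.where(hit, s, -np.inf)
    r = s.max(axis=1)
    if not np.all(np.isfinite(r)):
        raise ValueError("centroid ray missed the outline; degenerate polygon")
    return r


# ---------------------------------------------------------------------------
# analytic shape constructors (handy for tests and calibration)

def circle(n: int = 300, radius: float = 1.0, center=(0.0, 0.0)) -> np.ndarray:
    t = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(t),
                            center[1] + radius * np.sin(t)])


def ellipse(n: int = 300, a: float = 2.0, b: float = 1.0, rotation: float = 0.0,
            center=(0.0, 0.0), phase: float = 0.0) -> np.ndarray:
    """Exact ellipse sampled uniformly in the parametric angle."""
    t = 2.0 * np.pi * np.arange(n) / n + phase
    x = a * np.cos(t)
    y = b * np.sin(t)
    ct, st = np.cos(rotation), np.sin(rotation)
    return np.column_stack([center[0] + ct * x - st * y,
                            center[1] + st * x + ct * y])


def rectangle(width: float, height: float, points_per_side: int = 75) -> np.ndarray:
    w, h = width / 2.0, height / 2.0
    s = np.linspace(-1.0, 1.0, points_per_side, endpoint=False)
    right = np.column_stack([np.full_like(s, w), s * h])
    top = np.column_stack([-s * w, np.full_like(s, h)])
    left = np.column_stack([np.full_like(s, -w), -s * h])
    bottom = np.column_stack([s * w, np.full_like(s, -h)])
    return np.vstack([right, top, left, bottom])
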