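"""Mirror-asymmetry index of a lesion outline.

The centered, aligned outline is resampled at m equal angular steps about
its centroid. For each tested axis, every resampled point is paired with the
point at the mirrored polar angle (theta -> -theta across x, theta ->
pi - theta across y) and the discrepancy is the absolute difference of the
coordinate perpendicular to the axis, |c| vs |c'|. The per-axis index is the
root mean square of these discrepancies; the lesion's index is the maximum
over the two axes. A shape mirror-symmetric about an axis scores exactly 0
on it.

Computed on the normalized outline (unit centroid size, principal axes), so
the index is dimensionless and invariant to position, rotation and scale.
A 2-D variant of the discrepancy (full Euclidean distance between a point
and its reflected partner) is available behind ``planar=True`` for
sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .efa import normalize_outline
from .outline import radial_profile


@dataclass(frozen=True)
class AsymmetryResult:
    a_x: float
    a_y: float
    index: float

    def __post_init__(self):
        if not np.isclose(self.index, max(self.a_x, self.a_y)):
            raise ValueError("index must be max(a_x, a_y)")


def _polar_samples(outline: np.ndarray, m: int):
    r = radial_profile(outline, m, center=(0.0, 0.0))
    theta = 2.0 * np.pi * np.arange(m) / m
    return r, theta


def asymmetry_axis(outline: np.ndarray, axis: str, m: int = 360,
                   planar: bool = False, assume_normalized: bool = True) -> float:
    """RMS mirror discrepancy of a centered outline about one axis.

    ``outline`` must already be centered (use :func:`asymmetry_index` for the
    full normalize-then-score path). ``m`` must be even so every angle has an
    exact mirror partner on the grid.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    if m % 2:
        raise ValueError("m must be even")
    pts = np.asarray(outline, dtype=float)
    if not assume_normalized:
        pts = normalize_outline(pts)
    r, theta = _polar_samples(pts, m)
    idx = np.arange(m)
    if axis == "x":  # mirror theta -> -theta, compare |y|
        partner = (-idx) % m
        coord = np.abs(r * np.sin(theta))
    else:  # mirror theta -> pi - theta, compare |x|
        partner = (m // 2 - idx) % m
        coord = np.abs(r * np.cos(theta))
    if planar:
        x, y = r * np.cos(theta), r * np.sin(theta)
        if axis == "x":
            d = np.hypot(x - x[partner], np.abs(y) - np.abs(y[partner]))
        else:
            d = np.hypot(np.abs(x) - np.abs(x[partner]), y - y[partner])
    else:
        d = np.abs(coord - coord[partner])
    return float(np.sqrt(np.mean(d ** 2)))


def asymmetry_index(outline: np.ndarray, m: int = 360,
                    planar: bool = False) -> AsymmetryResult:
    """Normalize the outline, score both axes, return the maximum.

    The normalized outline is rescaled to unit RMS centroid distance
    (multiplying the unit-centroid-size outline by sqrt(n)), so the index
    reads as a fraction of the typical lesion radius.
    """
    pts = normalize_outline(outline)
    pts = pts * np.sqrt(len(pts))
    a_x = asymmetry_axis(pts, "x", m=m, planar=planar)
    a_y = asymmetry_axis(pts, "y", m=m, planar=planar)
    return AsymmetryResult(a_x=a_x, a_y=a_y, index=max(a_x, a_y))
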