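"""Refinement of coarse lesion masks and boundary extraction.

The input is an RGB photograph plus a rough prior mask (an expert's or the
generator's coarse delineation). Pixels are clustered on their RGB values
with k-means (k = 4 by default); the clusters lying mostly inside the prior
are taken as lesion, cleaned with a morphological closing, reduced to the
largest connected component with holes filled, and traced to a fixed-length
boundary (300 points, equally spaced by arc length).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.morphology import closing as binary_closing, disk
from sklearn.cluster import KMeans

from .outline import ensure_ccw, resample_by_arclength, roll_to_start

log = logging.getLogger(__name__)


class SegmentationError(RuntimeError):
    """Raised when no cluster can be matched to the prior mask."""


@dataclass(frozen=True)
class LabelMap:
    labels: np.ndarray  # integer raster, values 0..k-1
    k: int

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("label map must be 2-D")
        if lab.min() < 0 or lab.max() >= self.k:
            raise ValueError("labels outside 0..k-1")


def cluster_pixels(image: np.ndarray, k: int = 4, seed: int = 0) -> LabelMap:
    """K-means on per-pixel RGB features; deterministic given ``seed``."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3 or img.size == 0:
        raise ValueError("expected a non-empty RGB image")
    if k < 2:
        raise ValueError("k must be >= 2")
    flat = img.reshape(-1, 3)
    n_distinct = min(len(np.unique(flat, axis=0)), k)
    if n_distinct < k:
        log.warning("image has only %d distinct colours for k=%d; "
                    "some clusters will be empty", n_distinct, k)
    km = KMeans(n_clusters=n_distinct, n_init=4, random_state=seed)
    labels = km.fit_predict(flat)
    return LabelMap(labels=labels.reshape(img.shape[:2]), k=k)


def refine_lesion_mask(labels: LabelMap, prior_mask: np.ndarray,
                       inside_fraction: float = 0.5,
                       min_prior_coverage: float = 0.05,
                       closing_radius: int = 5) -> np.ndarray:
    """Select the clusters lying mostly inside the prior and clean them up.

    A cluster counts as lesion when more than ``inside_fraction`` of its
    pixels fall inside the prior mask and it covers at least
    ``min_prior_coverage`` of the prior's area. The union is closed with a
    disk, reduced to its largest connected component, and hole-filled, so
    the result is a single simply connected region.
    """
    prior = np.asarray(prior_mask, dtype=bool)
    if prior.shape != labels.labels.shape:
        raise ValueError("prior mask and label map dimensions differ")
    prior_area = prior.sum()
    if prior_area == 0:
        raise SegmentationError("empty prior mask")
    selected = np.zeros_like(prior)
    chosen = []
    for c in range(labels.k):
        in_cluster = labels.labels == c
        n_c = in_cluster.sum()
        if n_c == 0:
            continue
        overlap = (in_cluster & prior).sum()
        if overlap / n_c > inside_fraction and overlap / prior_area >= min_prior_coverage:
            selected |= in_cluster
            chosen.append(c)
    if not chosen:
        raise SegmentationError("no cluster lies mostly inside the prior mask")
    log.debug("selected clusters %s", chosen)
    closed = binary_closing(selected, disk(closing_radius))
    comp, n_comp = ndimage.label(closed)
    if n_comp == 0:
        raise SegmentationError("selected clusters vanished after closing")
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, np.arange(1, n_comp + 1))
    keep = comp == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(keep)


def extract_outline(mask: np.ndarray, n_points: int = 300) -> np.ndarray:
    """Trace the outer boundary and resample it to ``n_points`` points
    equally spaced by arc length, counter-clockwise, starting at the point
    of maximum x (tie: maximum y). Coordinates are (x, y) pixel centres in
    image convention (y downward)."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    _, n_comp = ndimage.label(m)
    if n_comp != 1:
        raise ValueError(f"mask must have exactly one connected component, got {n_comp}")
    padded = np.pad(m, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    boundary = max(contours, key=len)  # outer boundary is the longest
    xy = boundary[:, ::-1] - 1.0  # (row, col) -> (x, y), undo padding
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    xy = ensure_ccw(xy)
    xy = roll_to_start(xy)
    return resample_by_arclength(xy, n_points)


def image_to_math(outline: np.ndarray, height: int) -> np.ndarray:
    """Convert an image-convention outline (y downward) to the y-upward
    mathematical convention used by the morphometric modules."""
    out = np.asarray(outline, dtype=float).copy()
    out[:, 1] = (height - 1) - out[:, 1]
    return ensure_ccw(out)


def segment_lesion(image: np.ndarray, prior_mask: np.ndarray, k: int = 4,
                   n_points: int = 300, seed: int = 0,
                   closing_radius: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Full refinement chain: cluster -> refine -> trace. Returns
    ``(refined_mask, outline)`` with the outline in image convention."""
    labels = cluster_pixels(image, k=k, seed=seed)
    mask = refine_lesion_mask(labels, prior_mask, closing_radius=closing_radius)
    return mask, extract_outline(mask, n_points=n_points)
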