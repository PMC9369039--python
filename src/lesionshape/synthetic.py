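"""Synthetic lesion cohort generator.

Emulates the shape contrast between benign and malignant (BCC / IEC / SCC
-like) skin lesions with a radial-harmonic outline model

    r(theta) = r_ellipse(theta) * (1 + sum_k amp_k cos(k theta + phi_k)
                                     + s * g(theta))

where the amplitudes control border irregularity per harmonic order, and
g is an odd von-Mises-style bump pair (a lobe on one side of a random axis
and a matching constriction on the other) that breaks mirror symmetry with
strength s. Outlines can be rendered as two-tone noisy RGB images with a
deliberately coarse prior mask, mimicking a photograph plus an expert's
rough delineation.

Everything is deterministic given a seed; cohort items derive independent
seeds from the cohort seed so any record can be regenerated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.measure import approximate_polygon
from skimage.morphology import dilation, disk

from .outline import as_outline, is_simple

MALIGNANT_CLASSES = ("BCC", "IEC", "SCC")
CLASS_LABELS = ("BEN",) + MALIGNANT_CLASSES

#: Class sizes of the curated clinical lesion cohort the generator emulates.
DEFAULT_COUNTS = {"BEN": 588, "BCC": 239, "IEC": 78, "SCC": 88}


@dataclass(frozen=True)
class ShapeSpec:
    """Deterministic description of one lesion outline."""

    aspect_ratio: float = 1.0
    irregularity_amplitudes: tuple = ()  # per harmonic order 2, 3, ...
    asymmetry_strength: float = 0.0
    rotation: float = 0.0
    n_points: int = 300

    def __post_init__(self):
        amps = tuple(float(a) for a in self.irregularity_amplitudes)
        object.__setattr__(self, "irregularity_amplitudes", amps)
        if self.aspect_ratio <= 0 or not np.isfinite(self.aspect_ratio):
            raise ValueError("aspect_ratio must be a positive finite real")
        if any(a < 0 or not np.isfinite(a) for a in amps):
            raise ValueError("irregularity amplitudes must be finite and >= 0")
        if self.asymmetry_strength < 0:
            raise ValueError("asymmetry_strength must be >= 0")
        if self.n_points < 16:
            raise ValueError("n_points must be >= 16")
        # worst-case radial multiplier; the odd bump peaks at |g| <= 1
        worst = sum(amps) + self.asymmetry_strength
        if worst >= 0.95:
            raise ValueError(
                f"total perturbation {worst:.2f} risks radius collapse (>= 0.95)")


@dataclass(frozen=True)
class ClassShapeDistribution:
    """Half-normal amplitude scales and lognormal aspect spread for one class.

    ``amp_scales[k]`` is the half-normal scale of the radial harmonic of
    order k+2; ``asym_scale`` the half-normal scale of the odd-bump strength.
    """

    aspect_mean: float = 1.3
    aspect_sigma: float = 0.15  # lognormal sigma around aspect_mean
    amp_scales: tuple = (0.01, 0.008, 0.006, 0.004, 0.003, 0.002)
    asym_scale: float = 0.05

    def sample(self, rng: np.random.Generator) -> ShapeSpec:
        aspect = float(self.aspect_mean * rng.lognormal(0.0, self.aspect_sigma))
        amps = np.abs(rng.normal(0.0, self.amp_scales))
        asym = float(np.abs(rng.normal(0.0, self.asym_scale)))
        total = float(amps.sum() + asym)
        if total >= 0.9:  # keep well clear of radius collapse
            shrink = 0.9 / total
            amps, asym = amps * shrink, asym * shrink
        return ShapeSpec(
            aspect_ratio=aspect,
            irregularity_amplitudes=tuple(amps),
            asymmetry_strength=asym,
            rotation=float(rng.uniform(0.0, 2.0 * np.pi)),
        )


def _amp_scales(base: float) -> tuple:
    """Half-normal amplitude scales decaying over harmonic orders 2..7."""
    decay = (1.0, 0.8, 0.6, 0.45, 0.32, 0.22)
    return tuple(base * d for d in decay)


#: Per-class presets: benign lesions are near-elliptical with mild baseline
#: asymmetry; the malignant classes get markedly rougher borders
#: (IEC > SCC > BCC) and stronger, more dispersed one-sided asymmetry, so
#: the two groups overlap on the asymmetry index alone but separate well on
#: border irregularity — the contrast the downstream analyses probe.
CLASS_PRESETS = {
    "BEN": ClassShapeDistribution(aspect_mean=1.25, aspect_sigma=0.12,
                                  amp_scales=_amp_scales(0.012),
                                  asym_scale=0.11),
    "BCC": ClassShapeDistribution(aspect_mean=1.30, aspect_sigma=0.20,
                                  amp_scales=_amp_scales(0.034),
                                  asym_scale=0.15),
    "IEC": ClassShapeDistribution(aspect_mean=1.35, aspect_sigma=0.22,
                                  amp_scales=_amp_scales(0.066),
                                  asym_scale=0.14),
    "SCC": ClassShapeDistribution(aspect_mean=1.35, aspect_sigma=0.22,
                                  amp_scales=_amp_scales(0.056),
                                  asym_scale=0.14),
}

#: A deliberately well-separated variant (amplified irregularity contrast)
#: used when the question is whether the chain can recover a clean signal,
#: not whether the realistic overlap is handled.
SEPARATED_PRESETS = {
    "BEN": ClassShapeDistribution(aspect_mean=1.25, aspect_sigma=0.12,
                                  amp_scales=_amp_scales(0.006),
                                  asym_scale=0.03),
    "BCC": ClassShapeDistribution(aspect_mean=1.30, aspect_sigma=0.20,
                                  amp_scales=_amp_scales(0.075),
                                  asym_scale=0.22),
    "IEC": ClassShapeDistribution(aspect_mean=1.35, aspect_sigma=0.22,
                                  amp_scales=_amp_scales(0.095),
                                  asym_scale=0.20),
    "SCC": ClassShapeDistribution(aspect_mean=1.35, aspect_sigma=0.22,
                                  amp_scales=_amp_scales(0.085),
                                  asym_scale=0.20),
}


@dataclass(frozen=True)
class CohortSpec:
    classes: dict = field(default_factory=lambda: {
        label: (CLASS_PRESETS[label], DEFAULT_COUNTS[label])
        for label in CLASS_LABELS})
    seed: int = 0

    def __post_init__(self):
        for label, (dist, count) in self.classes.items():
            if count < 1:
                raise ValueError(f"count for {label} must be >= 1")


@dataclass(frozen=True)
class LesionRecord:
    label: str
    seed: int
    spec: ShapeSpec
    outline: np.ndarray
    image: np.ndarray | None = None
    prior_mask: np.ndarray | None = None
    true_mask: np.ndarray | None = None


def _odd_bump(theta: np.ndarray, theta0: float, width: float = 0.55) -> np.ndarray:
    """Odd (g(-t) = -g(t) about theta0's axis) bump pair: a von-Mises lobe at
    theta0 and a matching constriction at -theta0 relative to that axis,
    normalised to peak magnitude 1."""
    kappa = 1.0 / width ** 2
    lobe = np.exp(kappa * (np.cos(theta - theta0) - 1.0))
    anti = np.exp(kappa * (np.cos(theta + theta0) - 1.0))
    g = lobe - anti
    peak = np.abs(g).max()
    return g / max(peak, 1e-6)


def generate_outline(spec: ShapeSpec, seed: int) -> np.ndarray:
    """One closed, simple outline realised from ``spec``.

    Harmonic phases and the asymmetry-bump axis are drawn from ``seed``;
    self-intersecting realisations (possible at extreme amplitudes) are
    re-drawn with fresh phases.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_points
    theta = 2.0 * np.pi * np.arange(n) / n
    a, b = spec.aspect_ratio, 1.0
    r_ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    for _ in range(20):
        mult = np.ones(n)
        for k, amp in enumerate(spec.irregularity_amplitudes, start=2):
            mult += amp * np.cos(k * theta + rng.uniform(0.0, 2.0 * np.pi))
        if spec.asymmetry_strength > 0:
            theta0 = rng.uniform(0.2, np.pi - 0.2)
            mult += spec.asymmetry_strength * _odd_bump(theta, theta0)
        if mult.min() <= 0.05:
            raise ValueError("radial perturbation collapsed the outline")
        r = r_ell * mult
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        ct, st = np.cos(spec.rotation), np.sin(spec.rotation)
        pts = pts @ np.array([[ct, -st], [st, ct]]).T
        if is_simple(pts):
            return pts
    raise ValueError("could not realise a simple outline for this spec")


def render_lesion(outline: np.ndarray, seed: int, size: int = 192,
                  noise_sigma: float = 8.0, blur_sigma: float = 1.0,
                  prior_tolerance: float = 4.0, prior_dilation: int = 7):
    """Two-tone raster of a lesion plus a deliberately coarse prior mask.

    Returns ``(image, prior_mask, true_mask)``. The outline is scaled to fit
    the raster with a margin; the prior is the filled outline simplified to
    ``prior_tolerance`` pixels and dilated, so it always contains the truth
    but traces it loosely, like a quick expert delineation.
    """
    pts = as_outline(outline)
    rng = np.random.default_rng(seed)
    c = pts.mean(axis=0)
    extent = np.abs(pts - c).max()
    margin = prior_dilation + 12
    scale = (size / 2.0 - margin) / extent
    if scale <= 0:
        raise ValueError("raster too small for outline extent")
    px = (pts - c) * scale + size / 2.0  # (x, y) in pixel units

    rr, cc = draw_polygon(px[:, 1], px[:, 0], shape=(size, size))
    true_mask = np.zeros((size, size), dtype=bool)
    true_mask[rr, cc] = True

    skin = np.array([202.0, 162.0, 140.0])
    lesion = np.array([118.0, 72.0, 62.0])
    img = np.empty((size, size, 3))
    img[:] = skin
    img[true_mask] = lesion
    if blur_sigma > 0:
        for ch in range(3):
            img[:, :, ch] = ndimage.gaussian_filter(img[:, :, ch], blur_sigma)
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    closed = np.vstack([px, px[:1]])[:, ::-1]  # (row, col) for skimage
    simplified = approximate_polygon(closed, tolerance=prior_tolerance)
    rr, cc = draw_polygon(simplified[:, 0], simplified[:, 1], shape=(size, size))
    prior = np.zeros((size, size), dtype=bool)
    prior[rr, cc] = True
    prior = dilation(prior | true_mask, disk(prior_dilation))
    return img, prior, true_mask


def item_seed(cohort_seed: int, index: int) -> int:
    """Stable per-item seed derived from the cohort seed."""
    return int(np.random.SeedSequence([cohort_seed, index]).generate_state(1)[0]
               % (2 ** 31))


def generate_cohort(spec: CohortSpec, render: bool = False,
                    render_kwargs: dict | None = None) -> list[LesionRecord]:
    """Labeled synthetic cohort; per-item seeds make every record
    independently reproducible."""
    records = []
    index = 0
    for label in sorted(spec.classes):
        dist, count = spec.classes[label]
        for _ in range(count):
            s = item_seed(spec.seed, index)
            rng = np.random.default_rng(s)
            shape = dist.sample(rng)
            out = generate_outline(shape, seed=s + 1)
            rec_kwargs = {}
            if render:
                img, prior, truth = render_lesion(out, seed=s + 2,
                                                  **(render_kwargs or {}))
                rec_kwargs = dict(image=img, prior_mask=prior, true_mask=truth)
            records.append(LesionRecord(label=label, seed=s, spec=shape,
                                        outline=out, **rec_kwargs))
            index += 1
    return records


def small_cohort_spec(n_ben: int = 120, n_bcc: int = 48, n_iec: int = 16,
                      n_scc: int = 18, seed: int = 0,
                      presets: dict | None = None) -> CohortSpec:
    """Scaled-down cohort keeping the default class proportions (~1/5)."""
    presets = CLASS_PRESETS if presets is None else presets
    counts = {"BEN": n_ben, "BCC": n_bcc, "IEC": n_iec, "SCC": n_scc}
    return CohortSpec(classes={lbl: (presets[lbl], counts[lbl])
                               for lbl in CLASS_LABELS}, seed=seed)
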