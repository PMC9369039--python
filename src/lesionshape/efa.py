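"""Elliptic Fourier analysis of closed outlines.

Decomposes the coordinate functions x(t), y(t) of a closed polygon,
parameterised by cumulative chord length t, into a harmonic series

    x(t) = A0 + sum_n a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T)
    y(t) = C0 + sum_n c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T)

using the exact piecewise-linear (chain-sum) coefficient formulas, so the
vertices need not be equally spaced. Each harmonic n contributes an ellipse
described by the quadruple (a_n, b_n, c_n, d_n).

Also provides outline normalisation (alignment, centering, unit centroid
size), the standard first-harmonic coefficient normalisation that removes
residual size / rotation / starting-point effects (a_1 -> 1, b_1 = c_1 -> 0),
per-harmonic power, and the "oscilloscope" alpha statistic measuring how far
an outline departs from its best-fit ellipse (alpha = 0 for an exact
ellipse).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.measure import EllipseModel

from .outline import (
    as_outline,
    centroid_size,
    cumulative_arclength,
    ensure_ccw,
)


@dataclass(frozen=True)
class EFACoefficients:
    """Harmonic quadruples (a_n, b_n, c_n, d_n) plus the DC offset (A0, C0)."""

    harmonics: int
    coeffs: np.ndarray  # shape (harmonics, 4), columns a, b, c, d
    dc: tuple[float, float]

    def __post_init__(self):
        c = np.asarray(self.coeffs, dtype=float)
        if c.shape != (self.harmonics, 4):
            raise ValueError("coeffs must have shape (harmonics, 4)")
        if self.harmonics < 1 or not np.all(np.isfinite(c)):
            raise ValueError("need >= 1 harmonic with finite coefficients")
        object.__setattr__(self, "coeffs", c)


@dataclass(frozen=True)
class DescriptorVector:
    """Normalized EFA descriptors: d_1 then (a, b, c, d) of harmonics 2..n;
    length 4 n - 3."""

    values: np.ndarray
    harmonics: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (4 * self.harmonics - 3,):
            raise ValueError("descriptor length must be 4*harmonics - 3")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class AlphaStatistic:
    alpha: float
    alpha_x: float
    alpha_y: float


# ---------------------------------------------------------------------------
# outline normalisation

def normalize_outline(outline: np.ndarray) -> np.ndarray:
    """Center, align and scale an outline.

    The centroid is moved to the origin, the leading eigenvector of the
    vertex covariance matrix is rotated onto +x (signs disambiguated so the
    third moment along each axis is non-negative), the result is re-oriented
    counter-clockwise, and the whole outline is scaled to unit centroid size.
    """
    pts = as_outline(outline).copy()
    pts -= pts.mean(axis=0)
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or evals[0] < 1e-12 * evals[-1]:
        raise ValueError("degenerate outline: (near-)zero covariance")
    rot = evecs[:, ::-1]  # columns: leading axis, minor axis
    q = pts @ rot
    for axis in (0, 1):
        if stats.skew(q[:, axis]) < 0:
            q[:, axis] = -q[:, axis]
    q = ensure_ccw(q)
    return q / centroid_size(q)


# ---------------------------------------------------------------------------
# decomposition / reconstruction

def efa_decompose(outline: np.ndarray, n_harmonics: int) -> EFACoefficients:
    """Elliptic Fourier coefficients by the exact chain-sum formulas."""
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    pts = as_outline(outline)
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    if not np.all(keep):  # zero-length segments contribute nothing
        d, dt = d[keep], dt[keep]
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * np.pi * t / T  # angle at each vertex, phi[0] = 0

    n = np.arange(1, n_harmonics + 1)[:, None]  # (H, 1)
    const = T / (2.0 * (n * np.pi) ** 2)
    dcos = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
    dsin = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    sx = d[:, 0] / dt
    sy = d[:, 1] / dt
    a = (const * (sx * dcos)).sum(axis=1)
    b = (const * (sx * dsin)).sum(axis=1)
    c = (const * (sy * dcos)).sum(axis=1)
    dd = (const * (sy * dsin)).sum(axis=1)

    # DC terms (mean of x(t), y(t) over one period)
    xi = np.cumsum(d[:, 0]) - sx * t[1:]
    delta = np.cumsum(d[:, 1]) - sy * t[1:]
    A0 = pts[0, 0] + (1.0 / T) * np.sum(sx / 2.0 * np.diff(t ** 2) + xi * dt)
    C0 = pts[0, 1] + (1.0 / T) * np.sum(sy / 2.0 * np.diff(t ** 2) + delta * dt)

    return EFACoefficients(
        harmonics=n_harmonics,
        coeffs=np.column_stack([a, b, c, dd]),
        dc=(float(A0), float(C0)),
    )


def efa_reconstruct(coeffs: EFACoefficients, n_points: int) -> np.ndarray:
    """Evaluate the truncated series at ``n_points`` equally spaced parameter
    values."""
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    t = np.arange(n_points) / n_points  # t / T
    n = np.arange(1, coeffs.harmonics + 1)[:, None]
    cosn = np.cos(2.0 * np.pi * n * t)
    sinn = np.sin(2.0 * np.pi * n * t)
    a, b, c, d = coeffs.coeffs.T
    x = coeffs.dc[0] + a @ cosn + b @ sinn
    y = coeffs.dc[1] + c @ cosn + d @ sinn
    return np.column_stack([x, y])


def harmonic_power(coeffs: EFACoefficients) -> tuple[np.ndarray, np.ndarray]:
    """Per-harmonic power (a^2+b^2+c^2+d^2)/2 and cumulative proportion of
    the total over the computed harmonics."""
    power = 0.5 * (coeffs.coeffs ** 2).sum(axis=1)
    total = power.sum()
    if total <= 0:
        raise ValueError("outline has zero harmonic power")
    return power, np.cumsum(power) / total


def choose_harmonics(power_vectors, threshold: float = 0.983,
                     max_harmonics: int = 19, drop_first: bool = True) -> int:
    """Smallest harmonic count whose mean cumulative power reaches
    ``threshold``, capped at ``max_harmonics``.

    The first harmonic is excluded from the cumulative budget by default:
    it carries the gross ellipse and dominates total power, so including it
    would make the rule insensitive to the border detail the extra harmonics
    are there to capture.
    """
    P = np.asarray(list(power_vectors), dtype=float)
    if P.ndim == 1:
        P = P[None, :]
    mean_power = P.mean(axis=0)
    start = 1 if drop_first and mean_power.size > 1 else 0
    tail = mean_power[start:]
    cum = np.cumsum(tail) / tail.sum()
    n = start + int(np.searchsorted(cum, threshold) + 1)
    return min(n, max_harmonics)


# ---------------------------------------------------------------------------
# first-harmonic coefficient normalisation

def _normalization_angles(coeffs: EFACoefficients) -> tuple[float, float, float]:
    """(theta, psi, scale): start-phase rotation, orientation, and the
    first-ellipse semi-major magnitude."""
    a1, b1, c1, d1 = coeffs.coeffs[0]
    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1),
                             a1 ** 2 + c1 ** 2 - b1 ** 2 - d1 ** 2)
    best = None
    for cand in (theta, theta + np.pi / 2.0, theta + np.pi, theta + 1.5 * np.pi):
        a_star = a1 * np.cos(cand) + b1 * np.sin(cand)
        c_star = c1 * np.cos(cand) + d1 * np.sin(cand)
        mag = np.hypot(a_star, c_star)
        if best is None or mag > best[0] + 1e-15:
            best = (mag, cand, a_star, c_star)
    scale, theta, a_star, c_star = best
    if scale <= 0:
        raise ValueError("degenerate first harmonic (zero semi-major axis)")
    psi = np.arctan2(c_star, a_star)
    return float(theta), float(psi), float(scale)


def normalized_coefficient_matrix(coeffs: EFACoefficients) -> np.ndarray:
    """All harmonics re-phased, de-rotated and rescaled by the first-harmonic
    ellipse; row 0 becomes (1, 0, 0, d1').

    The first-harmonic procedure leaves a two-fold ambiguity (start point at
    either end of the semi-major axis) under which every even harmonic
    changes sign. It is resolved intrinsically: the largest-magnitude
    even-harmonic entry is made positive, so the result does not depend on
    where the input sampling happened to start.
    """
    theta, psi, scale = _normalization_angles(coeffs)
    rot_psi = np.array([[np.cos(psi), np.sin(psi)],
                        [-np.sin(psi), np.cos(psi)]])
    out = np.empty_like(coeffs.coeffs)
    for j in range(coeffs.harmonics):
        n = j + 1
        rot_theta = np.array([[np.cos(n * theta), -np.sin(n * theta)],
                              [np.sin(n * theta), np.cos(n * theta)]])
        M = coeffs.coeffs[j].reshape(2, 2)
        out[j] = (rot_psi @ M @ rot_theta).ravel() / scale
    even = out[1::2]  # harmonics 2, 4, ... (0-based odd rows)
    if even.size:
        flat = even.ravel()
        k = int(np.argmax(np.abs(flat)))
        if flat[k] < 0:
            out[1::2] = -even
    return out


def normalize_coefficients(coeffs: EFACoefficients) -> DescriptorVector:
    """Descriptor vector after first-harmonic normalisation: the constants
    a_1 = 1, b_1 = c_1 = 0 are dropped, leaving d_1 and all higher-harmonic
    quadruples (length 4 n - 3; 73 for 19 harmonics)."""
    norm = normalized_coefficient_matrix(coeffs)
    values = np.concatenate([[norm[0, 3]], norm[1:].ravel()])
    return DescriptorVector(values=values, harmonics=coeffs.harmonics)


def mean_shape(coeff_list, n_points: int = 300) -> np.ndarray:
    """Mean outline of a group: average of normalized coefficient matrices,
    reconstructed at ``n_points``."""
    mats = [normalized_coefficient_matrix(c) for c in coeff_list]
    h = mats[0].shape[0]
    if any(m.shape[0] != h for m in mats):
        raise ValueError("all coefficient sets must share the harmonic count")
    mean = np.mean(mats, axis=0)
    return efa_reconstruct(EFACoefficients(harmonics=h, coeffs=mean, dc=(0.0, 0.0)),
                           n_points)


# ---------------------------------------------------------------------------
# oscilloscope alpha

def _ellipse_from_first_harmonic(coeffs: EFACoefficients):
    M = coeffs.coeffs[0].reshape(2, 2)
    U, S, _ = np.linalg.svd(M)
    theta = np.arctan2(U[1, 0], U[0, 0])
    return coeffs.dc[0], coeffs.dc[1], float(S[0]), float(max(S[1], 1e-12)), float(theta)


def _best_fit_ellipse(pts: np.ndarray):
    try:
        model = EllipseModel.from_estimate(pts)
        (xc, yc), (a, b) = model.center, model.axis_lengths
        theta = float(model.theta)
        if np.all(np.isfinite([xc, yc, a, b, theta])) and a > 0 and b > 0:
            return float(xc), float(yc), float(a), float(b), theta
    except Exception:
        pass
    return _ellipse_from_first_harmonic(efa_decompose(pts, 1))


def oscilloscope_alpha(outline: np.ndarray, normalize: bool = True) -> AlphaStatistic:
    """Deviation of the x and y coordinate traces from those of the best-fit
    ellipse, integrated (trapezoid rule) over the arc-length parameter.

    Each vertex is compared against the fitted ellipse at the vertex's own
    elliptical phase, so every exact ellipse scores alpha = 0 regardless of
    how it was sampled; border irregularities raise alpha. Computed on the
    normalized outline rescaled to unit RMS centroid distance, hence
    invariant to position, rotation and scale and expressed as a fraction of
    the typical lesion radius.
    """
    if normalize:
        pts = normalize_outline(outline)
        pts = pts * np.sqrt(len(pts))
    else:
        pts = as_outline(outline)
    xc, yc, a, b, theta = _best_fit_ellipse(pts)
    ct, st = np.cos(theta), np.sin(theta)
    u = pts - [xc, yc]
    ux = u[:, 0] * ct + u[:, 1] * st
    uy = -u[:, 0] * st + u[:, 1] * ct
    phase = np.arctan2(uy / b, ux / a)
    fx = xc + a * np.cos(phase) * ct - b * np.sin(phase) * st
    fy = yc + a * np.cos(phase) * st + b * np.sin(phase) * ct
    resid = pts - np.column_stack([fx, fy])

    t = cumulative_arclength(pts)
    t = t / t[-1]
    rx = np.abs(np.concatenate([resid[:, 0], resid[:1, 0]]))
    ry = np.abs(np.concatenate([resid[:, 1], resid[:1, 1]]))
    ax = float(np.trapezoid(rx, t))
    ay = float(np.trapezoid(ry, t))
    return AlphaStatistic(alpha=ax + ay, alpha_x=ax, alpha_y=ay)
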