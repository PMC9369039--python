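"""Multivariate and robust statistics for shape descriptors.

Covers the analysis layer between descriptors and classification: covariance
PCA with a cumulative-variance retention rule, Shapiro-Wilk normality
screening, two-group MANOVA (Hotelling-Lawley trace or Wilks' lambda),
Mahalanobis-distance group comparisons, robust descriptive summaries built
on the biweight midvariance, and Sellke-Berger calibration of p-values into
false positive risks.

The FPR calibration converts a p-value into the probability that a
"significant" result is a type-I error: the Sellke-Berger bound on the
likelihood ratio of null to alternative is B(p) = -e p ln p (valid for
p < 1/e), and with prior probability ``prior_real`` that a real effect
exists,

    FPR = (1 - prior_real) B / ((1 - prior_real) B + prior_real).

Under the conventional 0.5 prior this makes p = 0.003 correspond to a 4.5%
false positive risk; brackets are reported at priors 0.8 and 0.2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.covariance import LedoitWolf
from statsmodels.multivariate.manova import MANOVA

log = logging.getLogger(__name__)

P_MAX_FPR = 1.0 / np.e  # p-values above this are too weak to calibrate


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray         # samples x components
    loadings: np.ndarray       # variables x components
    variance_fractions: np.ndarray
    retained: int
    mean: np.ndarray

    @property
    def retained_scores(self) -> np.ndarray:
        return self.scores[:, :self.retained]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new samples into the retained score space."""
        return (np.asarray(X, dtype=float) - self.mean) @ self.loadings[:, :self.retained]


@dataclass(frozen=True)
class FPRResult:
    p_value: float
    prior_real: float
    fpr: float | None
    interval: tuple | None  # (fpr at prior 0.8, fpr at prior 0.2)
    valid: bool


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    statistic: float
    p_value: float
    fpr: FPRResult | None = None


@dataclass(frozen=True)
class RobustSummary:
    n: int
    min: float
    max: float
    median: float
    sqrt_bwmv: float
    q05: float
    q95: float
    mean: float
    sd: float
    skewness: float
    kurtosis: float


# ---------------------------------------------------------------------------
# PCA

def pca_reduce(X: np.ndarray, threshold: float = 0.95) -> PCAResult:
    """Covariance PCA (columns centered, not rescaled); ``retained`` is the
    smallest component count whose cumulative variance reaches ``threshold``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing or non-finite values in input")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total <= 0:
        raise ValueError("input has zero variance")
    fractions = var / total
    retained = int(np.searchsorted(np.cumsum(fractions), threshold) + 1)
    retained = min(retained, len(fractions))
    return PCAResult(scores=U * s, loadings=Vt.T,
                     variance_fractions=fractions, retained=retained, mean=mean)


# ---------------------------------------------------------------------------
# univariate tests

def normality_test(x, calibrate: bool = False) -> TestResult:
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: normality test undefined")
    w, p = sps.shapiro(x)
    return TestResult("shapiro_w", float(w), float(p),
                      fpr=fpr_calibrate(p) if calibrate and 0 < p < 1 else None)


# ---------------------------------------------------------------------------
# MANOVA

def manova_pair(A: np.ndarray, B: np.ndarray,
                statistic: str = "hotelling_lawley",
                calibrate: bool = True) -> TestResult:
    """Two-group MANOVA on score matrices with the same variable count.

    ``statistic`` selects the Hotelling-Lawley trace or Wilks' lambda; for
    two groups both lead to the same exact F, matching the two-sample
    Hotelling T-squared test.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the variable count")
    p = A.shape[1]
    n = A.shape[0] + B.shape[0]
    if min(A.shape[0], B.shape[0]) <= p:
        log.warning("group size <= %d variables; MANOVA F approximation "
                    "is unreliable here", p)
    names = {"hotelling_lawley": "Hotelling-Lawley trace",
             "wilks": "Wilks' lambda"}
    if statistic not in names:
        raise ValueError(f"unknown statistic {statistic!r}")
    if np.allclose(A.mean(axis=0), B.mean(axis=0), atol=1e-12):
        # no between-group variance: trace 0 / lambda 1, nothing to test
        value = 0.0 if statistic == "hotelling_lawley" else 1.0
        return TestResult(statistic, value, 1.0, fpr=None)
    cols = [f"v{j}" for j in range(p)]
    df = pd.DataFrame(np.vstack([A, B]), columns=cols)
    df["group"] = ["A"] * len(A) + ["B"] * len(B)
    mv = MANOVA.from_formula(" + ".join(cols) + " ~ group", data=df)
    tbl = mv.mv_test().results["group"]["stat"]
    value = float(tbl.loc[names[statistic], "Value"])
    p_value = float(tbl.loc[names[statistic], "Pr > F"])
    p_value = min(max(p_value, 0.0), 1.0)
    return TestResult(statistic, value, p_value,
                      fpr=fpr_calibrate(p_value) if calibrate and 0 < p_value < 1
                      else None)


def manova_auto(A: np.ndarray, B: np.ndarray, calibrate: bool = True) -> TestResult:
    """Hotelling-Lawley when pooled scores pass Shapiro-Wilk (alpha = 0.05)
    on every variable, Wilks' lambda otherwise."""
    pooled = np.vstack([np.atleast_2d(A), np.atleast_2d(B)])
    gaussian = all(normality_test(pooled[:, j]).p_value > 0.05
                   for j in range(pooled.shape[1]))
    return manova_pair(A, B, "hotelling_lawley" if gaussian else "wilks",
                       calibrate=calibrate)


# ---------------------------------------------------------------------------
# Mahalanobis distances

def _group_params(X: np.ndarray, shrinkage: bool):
    mu = X.mean(axis=0)
    if shrinkage:
        cov = LedoitWolf().fit(X).covariance_
    else:
        cov = np.cov(X.T, ddof=1)
    return mu, np.linalg.pinv(np.atleast_2d(cov))


def mahalanobis_distances(X: np.ndarray, reference: np.ndarray,
                          leave_one_out: bool = False,
                          shrinkage: bool = False) -> np.ndarray:
    """Distances of rows of ``X`` to the mean/covariance of ``reference``.

    With ``leave_one_out`` (for X is reference itself) each row is scored
    against the parameters estimated from the remaining rows, avoiding the
    optimistic bias of self-inclusion.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    R = np.atleast_2d(np.asarray(reference, dtype=float))
    if leave_one_out:
        d = np.empty(len(X))
        for i in range(len(X)):
            rest = np.delete(R, i, axis=0)
            mu, icov = _group_params(rest, shrinkage)
            diff = X[i] - mu
            d[i] = np.sqrt(diff @ icov @ diff)
        return d
    mu, icov = _group_params(R, shrinkage)
    diff = X - mu
    return np.sqrt(np.einsum("ij,jk,ik->i", diff, icov, diff))


def mahalanobis_analysis(groups: dict, calibrate: bool = True,
                         leave_one_out: bool = True) -> dict:
    """Pairwise comparison of within- vs between-group Mahalanobis distances.

    For each reference group the distances of its own members (leave-one-out)
    and of every other group's members to its mean/covariance are computed;
    each own-vs-other pair of distance distributions is tested with ANOVA if
    both pass Shapiro-Wilk, otherwise Kruskal-Wallis. Returns
    ``{"distances": {(ref, other): array}, "tests": {(ref, other): TestResult}}``
    (own-group distances appear under ``(ref, ref)``).
    """
    groups = {k: np.atleast_2d(np.asarray(v, dtype=float))
              for k, v in groups.items()}
    p = next(iter(groups.values())).shape[1]
    distances, tests = {}, {}
    for ref, Xr in groups.items():
        shrink = len(Xr) < p + 2
        if shrink:
            log.warning("group %s has n=%d < p+2=%d; using shrinkage covariance",
                        ref, len(Xr), p + 2)
        own = mahalanobis_distances(Xr, Xr, leave_one_out=leave_one_out,
                                    shrinkage=shrink)
        distances[(ref, ref)] = own
        for other, Xo in groups.items():
            if other == ref:
                continue
            d = mahalanobis_distances(Xo, Xr, shrinkage=shrink)
            distances[(ref, other)] = d
            try:
                gaussian = (normality_test(own).p_value > 0.05
                            and normality_test(d).p_value > 0.05)
            except ValueError:
                gaussian = False
            if gaussian:
                stat, pv = sps.f_oneway(own, d)
                name = "anova_f"
            else:
                stat, pv = sps.kruskal(own, d)
                name = "kruskal_h"
            pv = float(min(max(pv, 0.0), 1.0))
            tests[(ref, other)] = TestResult(
                name, float(stat), pv,
                fpr=fpr_calibrate(pv) if calibrate and 0 < pv < 1 else None)
    return {"distances": distances, "tests": tests}


# ---------------------------------------------------------------------------
# false positive risk

def sellke_berger_bound(p: float) -> float:
    """Sellke-Berger bound B(p) = -e p ln p on the null:alternative
    likelihood ratio; meaningful for p < 1/e."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    return float(-np.e * p * np.log(p))


def fpr_calibrate(p: float, prior_real: float = 0.5) -> FPRResult:
    """Calibrated false positive risk of a p-value.

    Returns ``valid=False`` (no FPR) when p exceeds 1/e ~ 0.368, where the
    bound breaks down and the result could not support the alternative
    anyway. The interval brackets the risk at priors 0.8 (optimistic) and
    0.2 (sceptical).
    """
    if not 0.0 < prior_real < 1.0:
        raise ValueError("prior_real must lie in (0, 1)")
    B = sellke_berger_bound(p)
    if p > P_MAX_FPR:
        return FPRResult(p_value=p, prior_real=prior_real, fpr=None,
                         interval=None, valid=False)

    def risk(prior):
        return (1.0 - prior) * B / ((1.0 - prior) * B + prior)

    return FPRResult(p_value=p, prior_real=prior_real, fpr=risk(prior_real),
                     interval=(risk(0.8), risk(0.2)), valid=True)


def format_fpr_percent(res: FPRResult, digits: int = 1) -> str:
    """Render as e.g. '3.3 +/- [0.8, 11.9]%'; '-' when not calibrated."""
    if not res.valid:
        return "-"
    lo, hi = (100 * v for v in res.interval)
    return (f"{100 * res.fpr:.{digits}f} +/- "
            f"[{lo:.{digits}f}, {hi:.{digits}f}]%")


# ---------------------------------------------------------------------------
# robust descriptives

def biweight_midvariance(x, c: float = 9.0) -> float:
    """Tukey biweight midvariance with tuning constant ``c`` applied to
    MAD-standardised deviations; robust analogue of the variance."""
    x = np.asarray(x, dtype=float)
    M = np.median(x)
    mad = np.median(np.abs(x - M))
    if mad == 0:
        log.warning("degenerate MAD = 0; biweight midvariance set to 0")
        return 0.0
    u = (x - M) / (c * mad)
    a = np.abs(u) < 1.0
    num = len(x) * np.sum(a * (x - M) ** 2 * (1 - u ** 2) ** 4)
    den = np.sum(a * (1 - u ** 2) * (1 - 5 * u ** 2)) ** 2
    return float(num / den)


def robust_summary(x) -> RobustSummary:
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("robust summary needs n >= 4")
    return RobustSummary(
        n=int(x.size),
        min=float(x.min()),
        max=float(x.max()),
        median=float(np.median(x)),
        sqrt_bwmv=float(np.sqrt(biweight_midvariance(x))),
        q05=float(np.quantile(x, 0.05)),
        q95=float(np.quantile(x, 0.95)),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        skewness=float(sps.skew(x)),
        kurtosis=float(sps.kurtosis(x)),
    )
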