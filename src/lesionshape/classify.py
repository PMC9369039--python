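"""Benign-vs-malignant classification experiments.

Four feature sets are compared with an RBF-kernel SVM:

1. ``asymmetry_only``   - the scalar asymmetry index;
2. ``efa_pcs``          - PC scores of the EFA descriptors (95% rule);
3. ``efa_pcs_plus_asymmetry`` - feature set 2 with the asymmetry index
   appended as an extra column;
4. ``combined_pca``     - PCA of [descriptors || asymmetry index] after
   per-column standardisation.

Each experiment makes a stratified 70/30 split, tunes cost c and gamma by
Bayesian optimisation (random initialisation followed by Expected
Improvement under a Gaussian-process surrogate) of the 10-fold
cross-validated balanced accuracy on the training split, refits at the
optimum and reports imbalance-aware metrics (accuracy, precision, recall,
F1, PR-AUC) with a column-normalised confusion matrix, malignant positive.

By default all dimension-reduction statistics (PCA loadings, scaler) are
fitted on the training split only and applied to the test split. The
``pca_before_split`` switch restores the whole-dataset PCA order used by
protocols that reduce before splitting, which leaks test-set variance into
the features and is kept only for comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    confusion_matrix,
)
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .stats import pca_reduce

log = logging.getLogger(__name__)

FEATURE_SETS = ("asymmetry_only", "efa_pcs", "efa_pcs_plus_asymmetry",
                "combined_pca")

#: log10 search box for (c, gamma)
C_BOUNDS = (-3.0, 3.0)
GAMMA_BOUNDS = (-4.0, 2.0)


@dataclass(frozen=True)
class ExperimentSpec:
    feature_set: str
    split_fraction: float = 0.7
    folds: int = 10
    boa_iterations: int = 50
    boa_init: int = 10
    seed: int = 0
    pca_threshold: float = 0.95

    def __post_init__(self):
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass(frozen=True)
class EvalReport:
    feature_set: str
    accuracy: float
    balanced_accuracy: float
    precision: float
    recall: float
    f1: float
    pr_auc: float
    confusion: np.ndarray  # 2x2, column-normalised percent, cols = true class
    best_c: float
    best_gamma: float
    cv_score: float
    n_train: int = 0
    n_test: int = 0

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("feature_set", "accuracy", "balanced_accuracy", "precision",
              "recall", "f1", "pr_auc", "best_c", "best_gamma", "cv_score",
              "n_train", "n_test")}
        d["confusion_percent"] = np.asarray(self.confusion).tolist()
        return d


# ---------------------------------------------------------------------------
# feature construction

class FeatureBuilder:
    """Fits the transformations behind one feature set on training data and
    applies them to new data, so nothing about the test split leaks into the
    features."""

    def __init__(self, feature_set: str, pca_threshold: float = 0.95):
        if feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {feature_set!r}")
        self.feature_set = feature_set
        self.pca_threshold = pca_threshold
        self._pca = None
        self._scaler = None

    def fit(self, descriptors: np.ndarray, asym: np.ndarray) -> "FeatureBuilder":
        D = np.asarray(descriptors, dtype=float)
        a = np.asarray(asym, dtype=float).reshape(-1, 1)
        if self.feature_set in ("efa_pcs", "efa_pcs_plus_asymmetry"):
            self._pca = pca_reduce(D, self.pca_threshold)
        elif self.feature_set == "combined_pca":
            self._scaler = StandardScaler().fit(np.hstack([D, a]))
            Z = self._scaler.transform(np.hstack([D, a]))
            self._pca = pca_reduce(Z, self.pca_threshold)
        return self

    def transform(self, descriptors: np.ndarray, asym: np.ndarray) -> np.ndarray:
        D = np.asarray(descriptors, dtype=float)
        a = np.asarray(asym, dtype=float).reshape(-1, 1)
        if self.feature_set == "asymmetry_only":
            return a
        if self.feature_set == "efa_pcs":
            return self._pca.transform(D)
        if self.feature_set == "efa_pcs_plus_asymmetry":
            return np.hstack([self._pca.transform(D), a])
        Z = self._scaler.transform(np.hstack([D, a]))
        return self._pca.transform(Z)

    def fit_transform(self, descriptors, asym) -> np.ndarray:
        return self.fit(descriptors, asym).transform(descriptors, asym)


def build_feature_sets(descriptors: np.ndarray, asym: np.ndarray,
                       pca_threshold: float = 0.95) -> dict:
    """All four feature matrices fitted on the full data (the original
    pre-split protocol). Rows must be aligned across inputs."""
    D = np.asarray(descriptors, dtype=float)
    a = np.asarray(asym, dtype=float)
    if len(D) != len(a):
        raise ValueError("descriptor and asymmetry tables are not aligned")
    return {fs: FeatureBuilder(fs, pca_threshold).fit_transform(D, a)
            for fs in FEATURE_SETS}


# ---------------------------------------------------------------------------
# Bayesian optimisation (random init + Expected Improvement)

def boa_maximize(objective, bounds, n_init: int = 10, n_iter: int = 50,
                 rng=None, xi: float = 0.01):
    """Maximise a black-box function over a rectangular box.

    Random exploration seeds a Gaussian-process surrogate (Matern 5/2 with
    a small white-noise term); each subsequent point maximises the Expected
    Improvement acquisition over a dense random candidate set.

    Returns ``(best_x, best_value, history)``.
    """
    rng = np.random.default_rng(rng)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    dim = len(bounds)

    X = rng.uniform(lo, hi, size=(n_init, dim))
    y = np.array([objective(x) for x in X])

    kernel = (ConstantKernel(1.0, (1e-3, 1e3))
              * Matern(length_scale=np.ones(dim), length_scale_bounds=(1e-2, 1e2),
                       nu=2.5)
              + WhiteKernel(1e-6, (1e-8, 1e-1)))
    for _ in range(n_iter):
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                      n_restarts_optimizer=1, random_state=0)
        with warnings.catch_warnings():
            # surrogate hyperparameters pinned at a bound are harmless here
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(X, y)
            cand = rng.uniform(lo, hi, size=(2048, dim))
            mu, sigma = gp.predict(cand, return_std=True)
        best = y.max()
        sigma = np.maximum(sigma, 1e-12)
        z = (mu - best - xi) / sigma
        ei = (mu - best - xi) * norm.cdf(z) + sigma * norm.pdf(z)
        x_next = cand[int(np.argmax(ei))]
        y_next = objective(x_next)
        X = np.vstack([X, x_next])
        y = np.append(y, y_next)
    k = int(np.argmax(y))
    return X[k], float(y[k]), (X, y)


# ---------------------------------------------------------------------------
# training and evaluation

def _cv_objective(X, y, folds: int, seed: int):
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y))

    def objective(log_params):
        c = 10.0 ** log_params[0]
        gamma = 10.0 ** log_params[1]
        scores = []
        for tr, va in splits:
            clf = SVC(C=c, gamma=gamma, kernel="rbf")
            clf.fit(X[tr], y[tr])
            scores.append(balanced_accuracy_score(y[va], clf.predict(X[va])))
        return float(np.mean(scores))

    return objective


def tune_and_train(X_train: np.ndarray, y_train: np.ndarray,
                   spec: ExperimentSpec):
    """Optimise (c, gamma) by cross-validated balanced accuracy and refit on
    the full training split. Returns ``(model, best_c, best_gamma, cv_score)``.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training split contains a single class")
    objective = _cv_objective(np.asarray(X_train, dtype=float), y_train,
                              spec.folds, spec.seed)
    best_x, best_val, _ = boa_maximize(
        objective, [C_BOUNDS, GAMMA_BOUNDS], n_init=spec.boa_init,
        n_iter=spec.boa_iterations, rng=spec.seed)
    c, gamma = 10.0 ** best_x[0], 10.0 ** best_x[1]
    # sigmoid (Platt) calibration on training folds provides the class
    # probabilities needed for the precision-recall AUC
    model = CalibratedClassifierCV(
        SVC(C=c, gamma=gamma, kernel="rbf"), method="sigmoid",
        cv=StratifiedKFold(5, shuffle=True, random_state=spec.seed),
        ensemble=False)
    model.fit(X_train, y_train)
    return model, float(c), float(gamma), best_val


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray,
             feature_set: str = "", best_c: float = np.nan,
             best_gamma: float = np.nan, cv_score: float = np.nan,
             n_train: int = 0) -> EvalReport:
    """Test-set metrics with malignant (label 1) as the positive class."""
    y_test = np.asarray(y_test)
    if len(np.unique(y_test)) < 2:
        raise ValueError("test split contains a single class")
    y_pred = model.predict(X_test)
    scores = model.predict_proba(X_test)[:, list(model.classes_).index(1)]
    cm = confusion_matrix(y_test, y_pred, labels=[0, 1])
    tn, fp, fn, tp = cm.ravel()
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    col_pct = 100.0 * cm.T / cm.sum(axis=1)  # columns = true class
    return EvalReport(
        feature_set=feature_set,
        accuracy=float((tp + tn) / cm.sum()),
        balanced_accuracy=float(balanced_accuracy_score(y_test, y_pred)),
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        pr_auc=float(average_precision_score(y_test, scores)),
        confusion=col_pct,
        best_c=best_c, best_gamma=best_gamma, cv_score=cv_score,
        n_train=n_train, n_test=len(y_test))


def run_experiment(descriptors: np.ndarray, asym: np.ndarray,
                   y: np.ndarray, spec: ExperimentSpec,
                   pca_before_split: bool = False) -> EvalReport:
    """One full feature-set experiment: split, build features, tune, test.

    ``y`` is binary with 1 = malignant. With ``pca_before_split`` the PCA /
    scaling is fitted on all samples before the split (the original order);
    otherwise on the training split only.
    """
    D = np.asarray(descriptors, dtype=float)
    a = np.asarray(asym, dtype=float)
    y = np.asarray(y, dtype=int)
    idx = np.arange(len(y))
    idx_tr, idx_te = train_test_split(
        idx, train_size=spec.split_fraction, stratify=y,
        random_state=spec.seed)
    builder = FeatureBuilder(spec.feature_set, spec.pca_threshold)
    if pca_before_split:
        builder.fit(D, a)
    else:
        builder.fit(D[idx_tr], a[idx_tr])
    X_tr = builder.transform(D[idx_tr], a[idx_tr])
    X_te = builder.transform(D[idx_te], a[idx_te])
    # columns standardised for the SVM (fit on the training split only)
    scaler = StandardScaler().fit(X_tr)
    X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
    model, c, gamma, cv = tune_and_train(X_tr, y[idx_tr], spec)
    return evaluate(model, X_te, y[idx_te], feature_set=spec.feature_set,
                    best_c=c, best_gamma=gamma, cv_score=cv,
                    n_train=len(idx_tr))
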