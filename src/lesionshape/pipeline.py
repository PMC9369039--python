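"""End-to-end orchestration of the lesion shape analysis.

A run walks the full chain: obtain outlines (synthetic cohort, or images +
prior masks through segmentation, or pre-extracted outline CSVs), compute
EFA descriptors and the oscilloscope alpha, compute asymmetry indices,
summarise and test the groups (robust descriptives, pairwise MANOVA and
Mahalanobis analyses with false-positive-risk calibration), and evaluate
the four SVM feature-set experiments. Every artifact is written as plain
CSV/JSON with the seed and configuration embedded, so any stage can be
re-run from its serialized inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import kruskal

from . import classify, efa, segmentation, stats, synthetic
from .asymmetry import asymmetry_index

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    mode: str = "synthetic"            # synthetic | images | outlines
    out_dir: str = "results/run"
    seed: int = 0
    counts: dict = field(default_factory=lambda: dict(synthetic.DEFAULT_COUNTS))
    segment_qc: int = 0                # render+segment this many items as QC
    input_dir: str | None = None       # images/outlines modes
    k: int = 4
    n_points: int = 300
    n_harmonics: int = 19
    harmonic_rule: str = "fixed"       # fixed | power
    power_threshold: float = 0.983
    pca_threshold: float = 0.95
    prior_real: float = 0.5
    split_fraction: float = 0.7
    folds: int = 10
    boa_iterations: int = 50
    boa_init: int = 10
    pca_before_split: bool = False
    asymmetry_samples: int = 360


# ---------------------------------------------------------------------------
# stage functions (importable on their own)

def cohort_outlines(config: RunConfig):
    """Labelled outlines according to the configured input mode."""
    if config.mode == "synthetic":
        spec = synthetic.CohortSpec(
            classes={lbl: (synthetic.CLASS_PRESETS[lbl], config.counts[lbl])
                     for lbl in config.counts},
            seed=config.seed)
        records = synthetic.generate_cohort(spec)
        ids = [f"{r.label}_{i:04d}" for i, r in enumerate(records)]
        return ids, [r.label for r in records], [r.outline for r in records]
    if config.mode == "outlines":
        manifest = pd.read_csv(Path(config.input_dir) / "manifest.csv")
        ids, labels, outlines = [], [], []
        for _, row in manifest.iterrows():
            df = pd.read_csv(Path(config.input_dir) / row["outline"])
            ids.append(str(row["sample_id"]))
            labels.append(str(row["label"]))
            outlines.append(df[["x", "y"]].to_numpy())
        return ids, labels, outlines
    if config.mode == "images":
        from skimage.io import imread
        manifest = pd.read_csv(Path(config.input_dir) / "manifest.csv")
        ids, labels, outlines = [], [], []
        for _, row in manifest.iterrows():
            img = imread(Path(config.input_dir) / row["image"])
            prior = imread(Path(config.input_dir) / row["prior_mask"]) > 127
            try:
                _, out = segmentation.segment_lesion(
                    img[:, :, :3], prior, k=config.k,
                    n_points=config.n_points, seed=config.seed)
            except segmentation.SegmentationError as exc:
                log.error("segmentation failed for %s: %s", row["sample_id"], exc)
                continue
            out = segmentation.image_to_math(out, img.shape[0])
            ids.append(str(row["sample_id"]))
            labels.append(str(row["label"]))
            outlines.append(out)
        return ids, labels, outlines
    raise ValueError(f"unknown mode {config.mode!r}")


def segmentation_qc(config: RunConfig) -> pd.DataFrame:
    """Render and re-segment the first ``segment_qc`` synthetic items and
    report mask agreement (IoU) for the refined and prior masks."""
    spec = synthetic.CohortSpec(
        classes={lbl: (synthetic.CLASS_PRESETS[lbl], config.counts[lbl])
                 for lbl in config.counts},
        seed=config.seed)
    records = synthetic.generate_cohort(spec)
    rng = np.random.default_rng(config.seed)
    pick = rng.choice(len(records), size=min(config.segment_qc, len(records)),
                      replace=False)
    rows = []
    for i in sorted(pick):
        r = records[i]
        img, prior, truth = synthetic.render_lesion(r.outline, seed=r.seed + 2)
        try:
            mask, _ = segmentation.segment_lesion(img, prior, k=config.k,
                                                  n_points=config.n_points,
                                                  seed=config.seed)
            iou = (mask & truth).sum() / (mask | truth).sum()
        except segmentation.SegmentationError:
            iou = np.nan
        iou_prior = (prior & truth).sum() / (prior | truth).sum()
        rows.append(dict(index=i, label=r.label, iou_refined=iou,
                         iou_prior=iou_prior))
    return pd.DataFrame(rows)


def descriptor_table(ids, outlines, n_harmonics: int):
    """EFA descriptors (one row per sample) plus the per-sample coefficient
    objects and alpha statistics."""
    rows, coeffs, alphas = [], [], []
    for out in outlines:
        norm_out = efa.normalize_outline(out)
        co = efa.efa_decompose(norm_out, n_harmonics)
        coeffs.append(co)
        rows.append(efa.normalize_coefficients(co).values)
        alphas.append(efa.oscilloscope_alpha(out).alpha)
    names = ["d1"] + [f"{ch}{h}" for h in range(2, n_harmonics + 1)
                      for ch in "abcd"]
    df = pd.DataFrame(rows, columns=names, index=pd.Index(ids, name="sample_id"))
    return df, coeffs, np.array(alphas)


def pick_harmonics(outlines, config: RunConfig) -> int:
    if config.harmonic_rule == "fixed":
        return config.n_harmonics
    powers = []
    for out in outlines:
        co = efa.efa_decompose(efa.normalize_outline(out), config.n_harmonics)
        powers.append(efa.harmonic_power(co)[0])
    n = efa.choose_harmonics(powers, threshold=config.power_threshold,
                             max_harmonics=config.n_harmonics)
    log.info("power rule selected %d harmonics", n)
    return n


def class_alpha_table(labels, coeffs, alphas) -> pd.DataFrame:
    """Per-class alpha: of the class mean shape, and the per-item mean."""
    labels = np.asarray(labels)
    rows = []
    for lbl in sorted(set(labels)):
        sel = labels == lbl
        mean_out = efa.mean_shape([c for c, s in zip(coeffs, sel) if s])
        rows.append(dict(label=lbl,
                         alpha_mean_shape=efa.oscilloscope_alpha(mean_out).alpha,
                         alpha_item_mean=float(np.mean(alphas[sel])),
                         n=int(sel.sum())))
    return pd.DataFrame(rows).set_index("label")


def asymmetry_table(ids, outlines, m: int = 360) -> pd.DataFrame:
    rows = []
    for out in outlines:
        r = asymmetry_index(out, m=m)
        rows.append(dict(a_x=r.a_x, a_y=r.a_y, index=r.index))
    return pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"))


def _test_to_dict(t: stats.TestResult) -> dict:
    d = dict(statistic_name=t.statistic_name, statistic=t.statistic,
             p_value=t.p_value)
    if t.fpr is not None:
        d["fpr_percent"] = None if not t.fpr.valid else 100 * t.fpr.fpr
        d["fpr_bracket_percent"] = (None if not t.fpr.valid else
                                    [100 * v for v in t.fpr.interval])
    return d


def group_statistics(labels, descriptors: pd.DataFrame,
                     asym: pd.DataFrame, config: RunConfig) -> dict:
    """Robust per-class asymmetry summaries plus PCA, pairwise MANOVA and
    Mahalanobis testing with FPR annotation — with and without the
    asymmetry index in the multivariate block."""
    labels = np.asarray(labels)
    malignant = np.isin(labels, synthetic.MALIGNANT_CLASSES)
    out = {"classes": sorted(set(labels))}

    summaries = {}
    for lbl in sorted(set(labels)):
        summaries[lbl] = asdict(stats.robust_summary(
            asym["index"][labels == lbl].to_numpy()))
    summaries["Malignant"] = asdict(stats.robust_summary(
        asym["index"][malignant].to_numpy()))
    summaries["Benign"] = asdict(stats.robust_summary(
        asym["index"][~malignant].to_numpy()))
    out["asymmetry_summaries"] = summaries
    kw_stat, kw_p = kruskal(asym["index"][malignant],
                            asym["index"][~malignant])
    out["asymmetry_benign_vs_malignant"] = _test_to_dict(stats.TestResult(
        "kruskal_h", float(kw_stat), float(kw_p),
        fpr=stats.fpr_calibrate(float(kw_p)) if 0 < kw_p < 1 else None))

    def multivariate_block(X: np.ndarray) -> dict:
        pca = stats.pca_reduce(X, config.pca_threshold)
        scores = pca.retained_scores
        pooled_w = stats.normality_test(scores.ravel(), calibrate=True)
        block = {
            "n_components_retained": pca.retained,
            "pooled_shapiro": _test_to_dict(pooled_w),
        }
        pair_tests = {}
        for i, la in enumerate(sorted(set(labels))):
            for lb in sorted(set(labels))[i + 1:]:
                t = stats.manova_auto(scores[labels == la], scores[labels == lb])
                pair_tests[f"{la}|{lb}"] = _test_to_dict(t)
        t = stats.manova_auto(scores[~malignant], scores[malignant])
        pair_tests["Benign|Malignant"] = _test_to_dict(t)
        block["manova"] = pair_tests

        groups = {lbl: scores[labels == lbl] for lbl in sorted(set(labels))}
        maha = stats.mahalanobis_analysis(groups)
        block["mahalanobis"] = {f"{a}|{b}": _test_to_dict(t)
                                for (a, b), t in maha["tests"].items()}
        pooled = stats.mahalanobis_analysis(
            {"Benign": scores[~malignant], "Malignant": scores[malignant]})
        block["mahalanobis_benign_vs_malignant"] = _test_to_dict(
            pooled["tests"][("Benign", "Malignant")])
        return block

    D = descriptors.to_numpy()
    out["efa_only"] = multivariate_block(D)
    combo = np.hstack([D, asym[["index"]].to_numpy()])
    combo = (combo - combo.mean(axis=0)) / combo.std(axis=0)
    out["efa_plus_asymmetry"] = multivariate_block(combo)
    return out


def classification_experiments(labels, descriptors: pd.DataFrame,
                               asym: pd.DataFrame, config: RunConfig) -> dict:
    y = np.isin(np.asarray(labels), synthetic.MALIGNANT_CLASSES).astype(int)
    reports = {}
    for fs in classify.FEATURE_SETS:
        spec = classify.ExperimentSpec(
            feature_set=fs, split_fraction=config.split_fraction,
            folds=config.folds, boa_iterations=config.boa_iterations,
            boa_init=config.boa_init, seed=config.seed,
            pca_threshold=config.pca_threshold)
        rep = classify.run_experiment(descriptors.to_numpy(),
                                      asym["index"].to_numpy(), y, spec,
                                      pca_before_split=config.pca_before_split)
        reports[fs] = rep.to_dict()
        log.info("experiment %s: balanced accuracy %.3f", fs,
                 rep.balanced_accuracy)
    return reports


# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ids, labels, outlines = cohort_outlines(config)
    n_harm = pick_harmonics(outlines, config)
    desc, coeffs, alphas = descriptor_table(ids, outlines, n_harm)
    asym = asymmetry_table(ids, outlines, m=config.asymmetry_samples)
    alpha_cls = class_alpha_table(labels, coeffs, alphas)

    long = pd.concat(
        [pd.DataFrame({"sample_id": i, "point_index": np.arange(len(o)),
                       "x": o[:, 0], "y": o[:, 1]})
         for i, o in zip(ids, outlines)], ignore_index=True)
    long.to_csv(out_dir / "outlines.csv", index=False)
    desc_out = desc.copy()
    desc_out.insert(0, "label", labels)
    desc_out.to_csv(out_dir / "descriptors.csv")
    asym_out = asym.copy()
    asym_out.insert(0, "label", labels)
    asym_out.to_csv(out_dir / "asymmetry.csv")
    alpha_cls.to_csv(out_dir / "alpha_by_class.csv")

    report = {
        "config": asdict(config),
        "n_samples": len(ids),
        "n_harmonics": n_harm,
        "n_descriptors": desc.shape[1],
        "alpha_by_class": alpha_cls.reset_index().to_dict(orient="records"),
        "statistics": group_statistics(labels, desc, asym, config),
        "classification": classification_experiments(labels, desc, asym,
                                                     config),
    }
    if config.segment_qc and config.mode == "synthetic":
        qc = segmentation_qc(config)
        qc.to_csv(out_dir / "segmentation_qc.csv", index=False)
        report["segmentation_qc"] = {
            "n": int(len(qc)),
            "median_iou_refined": float(qc["iou_refined"].median()),
            "median_iou_prior": float(qc["iou_prior"].median()),
        }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
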