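# lesionshape

Outline morphometrics for skin lesions: does the *shape* of a lesion — its
border irregularity and asymmetry — separate malignant (non-melanoma skin
cancer: basal cell, intraepithelial and squamous cell carcinoma) from benign
lesions? This package implements the full analysis chain for that question,
driven by a synthetic lesion generator so every stage is testable without
access to a clinical image library:

1. **Boundary refinement** — a coarse expert-style prior mask is refined to
   pixel level by k-means colour clustering (k = 4), morphological closing,
   and largest-component/hole-filling cleanup; the boundary is traced and
   resampled to 300 points equally spaced by arc length.
2. **Elliptic Fourier analysis (EFA)** — each closed outline's coordinate
   functions x(t), y(t) are decomposed into harmonic ellipses with
   coefficients (aₙ, bₙ, cₙ, dₙ), computed by the exact chain-sum formulas
   over the polygon's segments. After first-harmonic normalisation
   (a₁ → 1, b₁ = c₁ → 0), 19 harmonics yield 73 shape descriptors per
   lesion, invariant to position, size, rotation and starting point.
3. **Oscilloscope α** — a border-irregularity statistic: the trapezoidal
   integral of the deviation of the outline's coordinate traces from its
   best-fit ellipse. An exact ellipse scores α = 0; rough borders score
   higher.
4. **Asymmetry index** — per-axis RMS mirror discrepancy of the centered,
   aligned outline, a(x) = √(1/n Σ d(xᵢ, |x′ᵢ|)²); the lesion's index is
   max(a(x), a(y)). Mirror-symmetric shapes score exactly 0.
5. **Statistics with false-positive-risk calibration** — covariance PCA
   (95% variance retention), Shapiro–Wilk screening, pairwise MANOVA
   (Hotelling–Lawley / Wilks' Λ), Mahalanobis-distance comparisons, robust
   summaries (median, √biweight-midvariance, 5/95% quantiles). Every
   p-value is calibrated into a false positive risk through the
   Sellke–Berger bound B(p) = −e·p·ln p:
   FPR = (1−π)B / ((1−π)B + π) at prior π = 0.5, bracketed by π = 0.8/0.2
   (no calibration for p > 1/e ≈ 0.368). Under this rule p = 0.003
   corresponds to a 4.5% false positive risk.
6. **Classification** — four feature-set experiments (asymmetry alone; EFA
   PC scores; PC scores + asymmetry; joint PCA of both) with an RBF-SVM,
   stratified 70/30 split, and Expected-Improvement Bayesian optimisation
   of cost and gamma over the 10-fold cross-validated balanced accuracy.
   Metrics are imbalance-aware: accuracy, precision, recall, F1 and the
   area under the precision–recall curve, malignant positive.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort of 202 lesions (120 benign, 48 BCC, 16 IEC, 18 SCC — one fifth of
the class proportions the generator emulates):

```
python analysis/01_generate_cohort.py
python analysis/02_segment_boundaries.py
python analysis/03_shape_descriptors.py
python analysis/04_group_statistics.py
python analysis/05_classification.py
```

Output from a run at seed 0 (summary tables land in `results/`):

```
median IoU: prior 0.830 -> refined 0.978

alpha of the class mean shapes (benign should be lowest):
BCC    0.0102
BEN    0.0066
IEC    0.0177
SCC    0.0237

asymmetry index, median (sqrt BWMV):
  BEN        0.024 (0.017)
  BCC        0.042 (0.019)
  IEC        0.065 (0.023)
  SCC        0.055 (0.016)
  Benign     0.024 (0.017)
  Malignant  0.050 (0.023)
benign vs malignant MANOVA (efa_only): p = 6.18e-07, FPR = 0.0024%
benign vs malignant MANOVA (efa_plus_asymmetry): p = 6.32e-08, FPR = 0.00028%

feature set                     acc    bal   prec    rec     f1  prauc
asymmetry_only                0.721  0.691  0.722  0.520  0.605  0.707
efa_pcs                       0.754  0.737  0.727  0.640  0.681  0.839
efa_pcs_plus_asymmetry        0.754  0.737  0.727  0.640  0.681  0.875
combined_pca                  0.918  0.912  0.917  0.880  0.898  0.962
```

Reading this: the k-means refinement roughly halves the mask error of the
coarse prior; benign lesions are the most elliptical (lowest mean-shape α)
and the least asymmetric, while malignant classes disperse more on the
asymmetry index; the benign/malignant contrast is multivariately conclusive
(FPR far below 6%); and the asymmetry index alone is the weakest classifier
while the joint PCA of EFA descriptors and asymmetry is the strongest —
the same qualitative ordering the statistics suggest.

A `lesionshape` CLI exposes the stages individually (`generate`, `segment`,
`efa`, `asymmetry`, `classify`, `run`); see `lesionshape --help`.

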