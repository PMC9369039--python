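# Methods

## The pipeline in one paragraph

A lesion enters as a closed outline — either generated synthetically or
traced from an image after prior-guided segmentation — and leaves as (i) a
73-dimensional elliptic-Fourier descriptor vector, (ii) an oscilloscope-α
border-irregularity score, and (iii) a mirror-asymmetry index. Group
contrasts are then tested multivariately (PCA → MANOVA / Mahalanobis) with
every p-value calibrated into a false positive risk, and the discriminative
value of the features is measured with RBF-SVM experiments.

## Synthetic cohort model

Outlines follow a radial-harmonic model around a base ellipse:

    r(θ) = r_ellipse(θ; aspect) · (1 + Σ_k amp_k cos(kθ + φ_k) + s·g(θ)),

with harmonic orders k = 2..7, phases φ_k drawn uniformly per lesion, and
g(θ) an odd von-Mises-style bump pair (a lobe at a random axis θ₀ and a
matching constriction at −θ₀, peak-normalised to 1) whose strength s
controls mirror asymmetry — producing the "lateral constriction" morphology
typical of irregular lesions. A radial model cannot self-intersect and is
re-drawn with fresh phases in the (never observed) event a realisation
fails the simplicity check; specs whose worst-case perturbation approaches
radius collapse are rejected at construction.

Class presets encode the contrast the analysis is designed to probe:
amplitudes are half-normal with class scales rising from benign (base
0.012) through BCC (0.034), SCC (0.056) to IEC (0.066), and asymmetry
strengths are half-normal with benign 0.11 versus malignant 0.14–0.165.
These defaults were chosen so the cohort reproduces the *qualitative*
structure reported for clinical lesions — benign outlines nearly
elliptical and concentrated, malignant outlines rougher with larger
asymmetry dispersion, the asymmetry index alone a weak univariate
classifier — not any particular printed value, which would require the
original (purchase-only) image library. A deliberately well-separated
preset family exists for tests that ask whether the chain can recover a
clean signal.

Rendering paints the filled outline in a lesion tone on a skin tone
(192×192 px), adds Gaussian pixel noise (σ = 8 of 255) and a mild blur
(σ = 1 px). The prior mask is the truth polygon simplified to 4 px
tolerance and dilated by 7 px — coarse but covering, like a quick expert
delineation. What the renderer does *not* emulate: skin texture, hair,
specular highlights, pigmentation gradients, un-pigmented lesion borders.
Passing segmentation tests therefore show the refinement logic is correct,
not that it would segment difficult clinical photographs.

Determinism: every record's seed derives from the cohort seed via
`SeedSequence([cohort_seed, index])`, so any lesion regenerates on its own.

## Segmentation

Pixels are clustered on raw RGB with k-means (k = 4, fixed seeded
initialisation). A cluster is lesion if >50% of its pixels lie inside the
prior mask *and* it covers ≥5% of the prior's area; the union is closed
with a 5 px disk, reduced to the largest connected component, and
hole-filled. The boundary is traced at the 0.5 iso-level of the padded
mask (8-connected foreground), oriented counter-clockwise, started at the
max-x vertex (tie: max y) and resampled to 300 points equally spaced by
arc length. Image coordinates (y down) are flipped to the mathematical
convention before morphometrics.

## Elliptic Fourier analysis

Coefficients are computed by the exact piecewise-linear chain sums over
the polygon's segments, parameterised by cumulative chord length — no
equal spacing is assumed. Outline normalisation centres the shape, rotates
the leading covariance eigenvector onto +x (per-axis sign fixed by
requiring non-negative third moments), restores counter-clockwise
orientation and scales to unit centroid size (root-summed-squared
centroid distances; the root-sum versus RMS choice only shifts a global
scale factor that cancels in the descriptors).

First-harmonic normalisation rescales by the first ellipse's semi-major
magnitude and removes its orientation and starting phase, leaving
a₁ = 1, b₁ = c₁ = 0; those constants are dropped, so n harmonics give
4n − 3 descriptors (73 at the default n = 19). The procedure has a
two-fold ambiguity — the start point may sit at either end of the
semi-major axis — under which every even harmonic flips sign; it is
resolved intrinsically by making the largest-magnitude even-harmonic entry
positive, which keeps descriptors independent of where the input sampling
happened to begin.

An automatic harmonic-count rule (smallest n whose cumulative power
reaches 98.3%, capped at 19) is provided; the cumulative budget excludes
harmonic 1, which carries the gross ellipse and would otherwise saturate
the rule at n = 1. The pipeline default is the fixed n = 19.

A caveat worth knowing: decompose→reconstruct is *not* an exact identity.
The reconstruction is re-parameterised by its own arc length, which
differs from the Fourier parameter wherever traversal speed varies, so
re-decomposed coefficients drift by ~2×10⁻⁵ on lesion-like shapes
(independent of sampling density). The tests pin this behaviour rather
than pretend it away.

## Oscilloscope α

α measures how far the coordinate traces of an outline deviate from those
of an ellipse. The implementation fits the best ellipse to the normalized
outline (direct least-squares conic fit; the first EFA harmonic as
fallback for degenerate fits), assigns each vertex its elliptical phase,
and integrates the absolute per-component deviation over the arc-length
parameter (trapezoid rule): α = α_x + α_y. Defining the reference
pointwise through the fitted ellipse — rather than fitting sinusoids
against arc length — makes α exactly 0 for *any* sampling of an exact
ellipse, which is the anchor the statistic is built on; a first-harmonic
sinusoid fit against arc length fails that anchor for non-circular
ellipses because x(s) is then not a single sinusoid. α is computed on the
normalized outline rescaled to unit RMS radius, so it reads as a fraction
of the typical lesion radius. Per-class α can be taken on the class mean
shape (reconstructed from averaged normalized coefficients) or as the
per-item mean; both are reported.

## Asymmetry index

The normalized outline (principal axes, unit RMS radius) is resampled at
m = 360 equal polar angles about the centroid; for non-star-shaped
outlines the outermost ray/boundary intersection is used. A point at angle
θ is paired with the point at the mirrored angle (−θ across x; π−θ across
y) and the discrepancy is the absolute difference of the coordinate
perpendicular to the axis, ||c| − |c′||. The per-axis index is the RMS of
these discrepancies and the lesion's index is the max over axes. The
angular pairing rule is what makes mirror-symmetric shapes score exactly
zero — the property the construction requires; the fully 2-D discrepancy
(Euclidean distance between a point and its reflected partner) is
available behind `planar=True` for sensitivity analysis. Scalar pairing,
m = 360, and the RMS-radius scale are the defaults throughout.

## Statistics

* **PCA** on the covariance matrix (descriptors share a scale); retention
  is the smallest component count reaching 95% cumulative variance. When
  the asymmetry index joins the descriptor block before PCA, columns are
  standardised first, since the index lives on a different scale.
* **MANOVA**: two-group tests via between/within SSCP with the standard F
  approximations (statsmodels backend); Hotelling–Lawley when pooled
  scores pass Shapiro–Wilk on every variable, Wilks' Λ otherwise. For two
  groups both reduce to the same exact F as Hotelling's T², which the
  tests verify against a closed-form oracle.
* **Mahalanobis analysis**: per reference group, leave-one-out distances
  of its own members (avoiding self-inclusion bias) versus plug-in
  distances of other groups' members; own-vs-other distributions compared
  by ANOVA when both pass normality, Kruskal–Wallis otherwise. Groups
  smaller than p + 2 fall back to Ledoit–Wolf shrinkage covariance, with
  a logged notice.
* **Robust summaries**: median, √biweight-midvariance (tuning constant 9
  on MAD-standardised deviations), [0.05, 0.95] quantile interval, plus
  classical mean/SD/skewness/kurtosis.
* **FPR calibration**: B(p) = −e·p·ln p; FPR = (1−π)B/((1−π)B+π) at prior
  π = 0.5 with a [π=0.8, π=0.2] bracket; p > 1/e is reported as
  uncalibrated ("-") rather than given a number. The 3σ convention
  p = 0.003 maps to 4.5%.

## Classification protocol

Stratified 70/30 split; features built *after* the split with PCA/scaler
statistics fitted on the training part only (the `pca_before_split` switch
restores whole-dataset PCA for comparison with protocols that reduce
before splitting — a documented leakage caveat of that order). All feature
matrices are column-standardised before the SVM, mirroring the default of
the kernlab/caret stack this protocol originates from. Hyperparameters are
searched over log₁₀ c ∈ [−3, 3], log₁₀ γ ∈ [−4, 2] — wide boxes, since no
narrower range is justified a priori — by 10 random evaluations followed
by Expected-Improvement acquisition under a Matérn-5/2 Gaussian-process
surrogate (50 iterations by default), maximising 10-fold cross-validated
balanced accuracy. The final model is refit on the full training split
with sigmoid (Platt) calibration on training folds to provide the class
probabilities behind the precision–recall AUC. The confusion matrix is
column-normalised per true class, malignant positive.

## Problem sizes

The analysis drivers and the test suite run the study at one fifth of the
emulated cohort (202 lesions) with 12-harmonic descriptors and a reduced
optimiser budget (6 random + 6 EI evaluations, 5 folds) for the
seed-ensemble comparisons; these sizes were chosen as the smallest at
which the group contrasts and feature-set rankings are stable across
seeds. The full-size defaults (993 lesions, 19 harmonics, 10 folds,
10 + 50 evaluations) remain the package defaults for real runs.

## Known limitations

* The generator produces star-shaped (radial) outlines only; deeply
  lobed or folded boundaries that defeat polar resampling do not occur in
  the synthetic cohort, though the ray-casting fallback handles them.
* Colour and texture carry no class signal by design; only shape is
  analysed, so synthetic results say nothing about pigmentation-based
  discrimination.
* α's absolute scale depends on the unit-RMS-radius convention; compare α
  values only within that convention.
* The Sellke–Berger calibration is a lower bound on the false positive
  risk under its likelihood-ratio model; it is reported as published
  convention, not as a posterior probability.
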