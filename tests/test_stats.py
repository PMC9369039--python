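"""Statistics layer: PCA retention, normality screening, MANOVA against the
Hotelling T-squared closed form, Mahalanobis comparisons, FPR calibration,
and robust descriptives."""

import numpy as np
import pytest
from scipy import stats as sps

from lesionshape import stats as ls


class TestPCA:
    def test_variance_fractions_sum_to_one(self, rng):
        res = ls.pca_reduce(rng.normal(0, 1, (40, 8)))
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(res.variance_fractions) <= 1e-12)

    def test_full_reconstruction_exact(self, rng):
        X = rng.normal(0, 1, (30, 6))
        res = ls.pca_reduce(X)
        back = res.scores @ res.loadings.T + res.mean
        assert np.allclose(back, X, atol=1e-10)

    def test_retained_matches_partial_sum_oracle(self, rng):
        for _ in range(5):
            X = rng.normal(0, 1, (50, 12)) @ np.diag(rng.uniform(0.1, 5, 12))
            res = ls.pca_reduce(X, threshold=0.9)
            cum = np.cumsum(res.variance_fractions)
            expected = int(np.argmax(cum >= 0.9)) + 1
            assert res.retained == expected

    def test_rank_deficient_handled(self, rng):
        X = rng.normal(0, 1, (20, 3))
        X = np.hstack([X, X[:, :1]])  # duplicated column
        res = ls.pca_reduce(X)
        assert res.variance_fractions[-1] == pytest.approx(0.0, abs=1e-12)

    def test_transform_matches_training_scores(self, rng):
        X = rng.normal(0, 1, (25, 5))
        res = ls.pca_reduce(X)
        assert np.allclose(res.transform(X), res.retained_scores, atol=1e-10)


class TestNormality:
    def test_gaussian_samples_usually_pass(self):
        passes = sum(
            ls.normality_test(np.random.default_rng(s).normal(0, 1, 50)).p_value
            > 0.05
            for s in range(100))
        assert passes >= 90

    def test_exponential_samples_usually_fail(self):
        fails = sum(
            ls.normality_test(np.random.default_rng(s).exponential(1, 200)).p_value
            < 0.01
            for s in range(100))
        assert fails >= 95

    def test_statistic_bounded_by_one(self, rng):
        assert ls.normality_test(rng.normal(0, 1, 80)).statistic <= 1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            ls.normality_test(np.ones(10))


class TestManova:
    def test_duplicated_group_degenerate(self, rng):
        A = rng.normal(0, 1, (30, 4))
        res = ls.manova_pair(A, A)
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)
        res_w = ls.manova_pair(A, A, "wilks")
        assert res_w.statistic == 1.0

    def test_hotelling_lawley_equals_t2_oracle(self, rng):
        A = rng.normal(0, 1, (30, 4))
        B = rng.normal(0.5, 1, (35, 4))
        res = ls.manova_pair(A, B)
        nA, nB, p = len(A), len(B), 4
        Sp = (((A - A.mean(0)).T @ (A - A.mean(0)))
              + ((B - B.mean(0)).T @ (B - B.mean(0)))) / (nA + nB - 2)
        d = A.mean(0) - B.mean(0)
        T2 = nA * nB / (nA + nB) * d @ np.linalg.solve(Sp, d)
        F = T2 * (nA + nB - p - 1) / ((nA + nB - 2) * p)
        p_oracle = sps.f.sf(F, p, nA + nB - p - 1)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-10)
        # two-group Wilks gives the same exact F
        assert ls.manova_pair(A, B, "wilks").p_value == pytest.approx(
            p_oracle, rel=1e-10)

    def test_separated_clouds_significant(self, rng):
        A = rng.normal(0, 1, (50, 3))
        B = rng.normal(5, 1, (50, 3))
        assert ls.manova_pair(A, B).p_value < 1e-6

    def test_auto_dispatch_uses_wilks_for_skewed_scores(self, rng):
        A = rng.lognormal(0, 1, (60, 2))
        B = rng.lognormal(0.3, 1, (60, 2))
        assert ls.manova_auto(A, B).statistic_name == "wilks"


class TestMahalanobis:
    def test_group_mean_at_distance_zero(self, rng):
        X = rng.normal(0, 1, (50, 4))
        d = ls.mahalanobis_distances(np.atleast_2d(X.mean(0)), X)
        assert d[0] == pytest.approx(0.0, abs=1e-10)

    def test_identical_populations_indistinguishable(self):
        ps = []
        for s in range(11):
            rng = np.random.default_rng(s)
            g = {"A": rng.normal(0, 1, (60, 4)), "B": rng.normal(0, 1, (60, 4))}
            ps.append(ls.mahalanobis_analysis(g)["tests"][("A", "B")].p_value)
        assert np.median(ps) > 0.1

    def test_squared_distances_follow_chi_square(self, rng):
        X = rng.normal(0, 1, (1000, 6))
        d = ls.mahalanobis_distances(X, X)
        ks = sps.kstest(d ** 2, "chi2", args=(6,)).statistic
        assert ks < 0.1

    def test_separated_groups_detected(self, rng):
        g = {"A": rng.normal(0, 1, (60, 4)), "B": rng.normal(2, 1, (60, 4))}
        res = ls.mahalanobis_analysis(g)
        assert res["tests"][("A", "B")].p_value < 1e-6
        assert len(res["distances"][("A", "A")]) == 60

    def test_small_group_uses_shrinkage(self, rng, caplog):
        g = {"A": rng.normal(0, 1, (5, 6)), "B": rng.normal(0, 1, (30, 6))}
        with caplog.at_level("WARNING"):
            ls.mahalanobis_analysis(g)
        assert "shrinkage" in caplog.text


class TestFPR:
    def test_three_sigma_threshold_maps_to_4_5_percent(self):
        res = ls.fpr_calibrate(0.003, prior_real=0.5)
        assert round(100 * res.fpr, 1) == 4.5

    def test_boundary_case_one_over_e(self):
        res = ls.fpr_calibrate(1 / np.e, prior_real=0.5)
        assert res.valid and res.fpr == pytest.approx(0.5, abs=1e-12)

    def test_weak_p_values_not_calibrated(self):
        res = ls.fpr_calibrate(0.5)
        assert not res.valid and res.fpr is None
        assert ls.format_fpr_percent(res) == "-"

    def test_monotone_in_p_and_prior(self):
        ps = np.linspace(0.001, 0.36, 50)
        fprs = [ls.fpr_calibrate(p).fpr for p in ps]
        assert np.all(np.diff(fprs) > 0)
        priors = np.linspace(0.1, 0.9, 9)
        by_prior = [ls.fpr_calibrate(0.01, pr).fpr for pr in priors]
        assert np.all(np.diff(by_prior) < 0)

    def test_interval_brackets_point_estimate(self):
        for p in (0.0005, 0.003, 0.05, 0.3):
            res = ls.fpr_calibrate(p)
            lo, hi = res.interval
            assert lo < res.fpr < hi

    def test_rejects_p_outside_unit_interval(self):
        for p in (0.0, 1.0, -0.1, 2.0):
            with pytest.raises(ValueError):
                ls.fpr_calibrate(p)


class TestRobustSummary:
    def test_constant_vector_zero_bwmv(self, caplog):
        with caplog.at_level("WARNING"):
            assert ls.biweight_midvariance(np.ones(10)) == 0.0
        assert "degenerate" in caplog.text

    def test_symmetric_sample(self):
        s = ls.robust_summary(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]))
        assert s.median == 0.0 and s.q05 <= -1 and s.q95 >= 1

    def test_bwmv_matches_formula_transcription(self, rng):
        x = rng.lognormal(0, 1, 500)
        # direct transcription, scalar loop
        M = float(np.median(x))
        mad = float(np.median(np.abs(x - M)))
        num = den = 0.0
        for xi in x:
            u = (xi - M) / (9 * mad)
            if abs(u) < 1:
                num += (xi - M) ** 2 * (1 - u ** 2) ** 4
                den += (1 - u ** 2) * (1 - 5 * u ** 2)
        oracle = len(x) * num / den ** 2
        assert ls.biweight_midvariance(x) == pytest.approx(oracle, abs=1e-12)

    def test_quantile_ordering_invariant(self, rng):
        s = ls.robust_summary(rng.normal(3, 2, 200))
        assert s.min <= s.q05 <= s.median <= s.q95 <= s.max
        assert s.sqrt_bwmv >= 0

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ls.robust_summary(np.array([1.0, 2.0, 3.0]))
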