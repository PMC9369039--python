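"""Elliptic Fourier analysis: chain-sum coefficients against a quadrature
oracle, normalisation invariances, harmonic power, and the alpha statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesionshape import efa
from lesionshape import outline as ol

from conftest import radial_shape


def quadrature_coefficients(outline, n_harmonics, samples=200_000):
    """Independent oracle: dense trapezoid integration of the Fourier
    integrals over the piecewise-linear x(t), y(t)."""
    pts = np.vstack([outline, outline[:1]])
    t = ol.cumulative_arclength(outline)
    T = t[-1]
    ts = np.linspace(0, T, samples + 1)
    x = np.interp(ts, t, pts[:, 0])
    y = np.interp(ts, t, pts[:, 1])
    coeffs = np.empty((n_harmonics, 4))
    for n in range(1, n_harmonics + 1):
        w = 2 * np.pi * n * ts / T
        coeffs[n - 1] = [
            2 / T * np.trapezoid(x * np.cos(w), ts),
            2 / T * np.trapezoid(x * np.sin(w), ts),
            2 / T * np.trapezoid(y * np.cos(w), ts),
            2 / T * np.trapezoid(y * np.sin(w), ts),
        ]
    dc = (np.trapezoid(x, ts) / T, np.trapezoid(y, ts) / T)
    return coeffs, dc


def similarity(points, rotation=0.0, scale=1.0, shift=(0.0, 0.0), roll=0):
    R = np.array([[np.cos(rotation), -np.sin(rotation)],
                  [np.sin(rotation), np.cos(rotation)]])
    return np.roll(points @ R.T * scale + np.asarray(shift), roll, axis=0)


TOY_POLYGONS = {
    "square": ol.rectangle(2, 2),
    "rectangle": ol.rectangle(3, 1),
    "triangle": np.array([[1.0, 0.0], [-0.5, 0.9], [-0.5, -0.9]]),
    "ellipse": ol.ellipse(120, 2, 1, rotation=0.3),
    "star": radial_shape([0.15, 0.0, 0.1], [0.5, 0.0, 1.7], n=120),
}


class TestDecompose:
    @pytest.mark.parametrize("name", sorted(TOY_POLYGONS))
    def test_matches_quadrature_oracle(self, name):
        poly = TOY_POLYGONS[name]
        co = efa.efa_decompose(poly, 6)
        oracle, dc = quadrature_coefficients(poly, 6)
        assert np.allclose(co.coeffs, oracle, atol=1e-6)
        assert np.allclose(co.dc, dc, atol=1e-6)

    def test_circle_power_in_first_harmonic(self):
        co = efa.efa_decompose(ol.circle(300), 10)
        power, cum = efa.harmonic_power(co)
        assert cum[0] > 0.999999
        assert np.abs(co.coeffs[1:]).max() < 1e-6

    def test_zero_length_segments_dropped(self, irregular_outline):
        doubled = np.repeat(irregular_outline, 2, axis=0)
        co1 = efa.efa_decompose(irregular_outline, 8)
        co2 = efa.efa_decompose(doubled, 8)
        assert np.allclose(co1.coeffs, co2.coeffs, atol=1e-9)

    def test_roundtrip_error_small_on_lesion_like_shape(self, irregular_outline):
        co = efa.efa_decompose(irregular_outline, 40)
        rec = efa.efa_reconstruct(co, 300)
        diam = np.ptp(irregular_outline, axis=0).max()
        from scipy.spatial import cKDTree
        dense = efa.efa_reconstruct(co, 3000)
        d, _ = cKDTree(dense).query(irregular_outline)
        assert d.mean() < 0.005 * diam
        assert rec.shape == (300, 2)

    def test_reconstruction_error_nonincreasing_in_harmonics(self, irregular_outline):
        from scipy.spatial import cKDTree
        errs = []
        for n in range(1, 41):
            co = efa.efa_decompose(irregular_outline, n)
            dense = efa.efa_reconstruct(co, 3000)
            d, _ = cKDTree(dense).query(irregular_outline)
            errs.append(d.mean())
        errs = np.array(errs)
        # allow the chord-discretisation noise floor (~1e-6 here)
        assert np.all(errs[1:] <= errs[:-1] * 1.01 + 1e-9)

    def test_decompose_reconstruct_near_fixed_point(self, irregular_outline):
        # decompose-reconstruct is not an exact identity: reconstruction is
        # re-parameterised by its own arc length, which differs from the
        # Fourier parameter wherever the traversal speed is non-uniform.
        # The map is approximately stable; discretisation adds ~1e-4 at 300
        # reconstruction points and the intrinsic drift is ~2e-5 here.
        co = efa.efa_decompose(irregular_outline, 15)
        again300 = efa.efa_decompose(efa.efa_reconstruct(co, 300), 15)
        assert np.allclose(co.coeffs, again300.coeffs, atol=2e-4)
        again5k = efa.efa_decompose(efa.efa_reconstruct(co, 5000), 15)
        assert np.allclose(co.coeffs, again5k.coeffs, atol=5e-5)


class TestReconstruct:
    def test_circle_roundtrip(self):
        # a 400-gon only approximates the circle to ~1/400^2
        co = efa.efa_decompose(ol.circle(400), 1)
        rec = efa.efa_reconstruct(co, 400)
        assert np.allclose(np.hypot(rec[:, 0], rec[:, 1]), 1.0, atol=1e-4)

    def test_first_harmonic_only_is_exact_ellipse(self):
        co = efa.EFACoefficients(1, np.array([[1.8, 0.4, -0.2, 0.9]]), (0.3, -0.1))
        rec = efa.efa_reconstruct(co, 300)
        assert efa.oscilloscope_alpha(rec).alpha < 1e-8


class TestHarmonicPower:
    def test_cumulative_monotone_and_final_one(self, irregular_outline):
        _, cum = efa.harmonic_power(efa.efa_decompose(irregular_outline, 20))
        assert np.all(np.diff(cum) >= 0)
        assert cum[-1] == pytest.approx(1.0, abs=1e-12)

    def test_choose_harmonics_matches_partial_sum_oracle(self, irregular_outline):
        power, _ = efa.harmonic_power(efa.efa_decompose(irregular_outline, 19))
        n = efa.choose_harmonics([power], threshold=0.983)
        # direct transcription of the rule on the first-harmonic-excluded tail
        tail = power[1:]
        cum = np.cumsum(tail) / tail.sum()
        expected = 1 + int(np.argmax(cum >= 0.983)) + 1
        assert n == min(expected, 19)


class TestNormalization:
    def test_outline_normalization_removes_similarity(self, irregular_outline):
        a = efa.normalize_outline(irregular_outline)
        b = efa.normalize_outline(
            similarity(irregular_outline, rotation=np.pi / 2, scale=3.0,
                       shift=(4.0, -2.0)))
        assert np.allclose(a, b, atol=1e-9)

    def test_axis_aligned_after_normalization(self):
        e = efa.normalize_outline(ol.ellipse(300, 2, 1, rotation=1.1))
        assert np.ptp(e[:, 0]) > np.ptp(e[:, 1])  # major axis on x

    def test_centroid_and_size_contracts(self, irregular_outline):
        out = efa.normalize_outline(irregular_outline)
        assert np.abs(out.mean(axis=0)).max() < 1e-12
        assert ol.centroid_size(out) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_outline_rejected(self):
        line = np.column_stack([np.linspace(0, 1, 10), np.zeros(10)])
        with pytest.raises(ValueError):
            efa.normalize_outline(np.vstack([line, line[::-1] + 1e-16]))

    def test_descriptor_length_73_at_19_harmonics(self, irregular_outline):
        co = efa.efa_decompose(irregular_outline, 19)
        assert len(efa.normalize_coefficients(co).values) == 73

    def test_normalized_first_quadruple(self, irregular_outline):
        mat = efa.normalized_coefficient_matrix(
            efa.efa_decompose(irregular_outline, 10))
        assert np.allclose(mat[0, :3], [1.0, 0.0, 0.0], atol=1e-10)

    @pytest.mark.parametrize("rotation,scale,roll", [
        (1.1, 3.0, 57), (2.7, 0.4, 150), (-0.3, 10.0, 299), (np.pi, 1.0, 10)])
    def test_descriptor_invariance(self, irregular_outline, rotation, scale, roll):
        d1 = efa.normalize_coefficients(
            efa.efa_decompose(irregular_outline, 12)).values
        moved = similarity(irregular_outline, rotation, scale, (5.0, -2.0), roll)
        d2 = efa.normalize_coefficients(efa.efa_decompose(moved, 12)).values
        assert np.allclose(d1, d2, atol=1e-8)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(rotation=st.floats(0, 2 * np.pi), scale=st.floats(0.1, 20),
           roll=st.integers(0, 299))
    def test_descriptor_invariance_property(self, rotation, scale, roll):
        base = radial_shape([0.08, 0.05, 0.03], [1.0, 2.2, 0.4], aspect=1.4)
        d1 = efa.normalize_coefficients(efa.efa_decompose(base, 10)).values
        moved = similarity(base, rotation, scale, (1.0, 1.0), roll)
        d2 = efa.normalize_coefficients(efa.efa_decompose(moved, 10)).values
        assert np.allclose(d1, d2, atol=1e-8)


class TestAlpha:
    @pytest.mark.parametrize("aspect,rotation,phase", [
        (1.0, 0.0, 0.0), (2.0, 0.7, 0.3), (3.5, -1.2, 1.0), (1.2, 2.9, 2.2)])
    def test_exact_ellipse_scores_zero(self, aspect, rotation, phase):
        e = ol.ellipse(300, aspect, 1.0, rotation=rotation, phase=phase)
        assert efa.oscilloscope_alpha(e).alpha < 1e-8

    def test_invariant_under_similarity(self, irregular_outline):
        a1 = efa.oscilloscope_alpha(irregular_outline).alpha
        a2 = efa.oscilloscope_alpha(
            similarity(irregular_outline, 0.9, 4.2, (3.0, 1.0))).alpha
        assert a1 == pytest.approx(a2, abs=1e-8)

    def test_monotone_in_irregularity_amplitude(self):
        prev = -1.0
        for amp in (0.01, 0.02, 0.04, 0.08):
            shape = radial_shape([0.0, 0.0, amp, 0.7 * amp], [0, 0, 1.0, 0.0])
            a = efa.oscilloscope_alpha(shape).alpha
            assert a > prev
            prev = a

    def test_components_sum_to_alpha(self, irregular_outline):
        st_ = efa.oscilloscope_alpha(irregular_outline)
        assert st_.alpha == pytest.approx(st_.alpha_x + st_.alpha_y)


class TestMeanShape:
    def test_mean_of_identical_shapes_reconstructs_them(self, irregular_outline):
        co = efa.efa_decompose(efa.normalize_outline(irregular_outline), 12)
        mean = efa.mean_shape([co, co], n_points=300)
        solo = efa.efa_reconstruct(
            efa.EFACoefficients(12, efa.normalized_coefficient_matrix(co),
                                (0.0, 0.0)), 300)
        assert np.allclose(mean, solo, atol=1e-12)
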