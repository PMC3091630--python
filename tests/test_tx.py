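"""Expression p.d.f. estimation, tail correction and depth prediction."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seqdesign.tx import (
    ExpressionPDF,
    TranscriptCounts,
    correct_pdf,
    cross_sample_predict,
    detection_prob,
    empirical_pdf,
    fit_power_law,
    normalized_expression,
    predict_detection,
    reliable_point,
    required_depth,
)


def point_mass_pdf(nu0: float) -> ExpressionPDF:
    edges = np.array([nu0 / 1.001, nu0 * 1.001])
    return ExpressionPDF(bin_edges=edges, density=np.array([1.0]))


class TestNormalizedExpression:
    def test_single_transcript(self):
        assert normalized_expression(TranscriptCounts({"a": 7})) == {"a": 1.0}

    def test_simple_split(self):
        nu = normalized_expression(TranscriptCounts({"a": 3, "b": 1}))
        assert nu == {"a": 0.75, "b": 0.25}

    def test_scale_invariance(self):
        base = normalized_expression(TranscriptCounts({"a": 3, "b": 9, "c": 12}))
        scaled = normalized_expression(TranscriptCounts({"a": 30, "b": 90, "c": 120}))
        assert base == scaled

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            normalized_expression(TranscriptCounts({}))


class TestDetectionProb:
    @pytest.mark.parametrize(
        "nu, depth, expected",
        [(0.0, 1000, 0.0), (1.0, 1, 1.0), (0.5, 0, 0.0)],
    )
    def test_edges(self, nu, depth, expected):
        assert detection_prob(nu, depth) == expected

    def test_poisson_limit(self):
        n = 10**7
        assert detection_prob(3.0 / n, n) == pytest.approx(1 - math.exp(-3), rel=1e-6)

    @given(st.floats(1e-8, 0.99), st.integers(0, 10**7))
    def test_monotone_in_depth(self, nu, depth):
        assert detection_prob(nu, depth + 1) >= detection_prob(nu, depth)


class TestReliablePoint:
    def test_single_read(self):
        assert reliable_point(1) == pytest.approx(0.95)

    def test_100k_reads_closed_form(self):
        assert reliable_point(10**5) == 1.0 - 0.05 ** (1.0 / 10**5)
        assert reliable_point(10**5) == pytest.approx(2.996e-5, rel=1e-3)

    def test_scales_as_inverse_reads(self):
        rs = [10**k for k in range(2, 8)]
        values = [reliable_point(r) for r in rs]
        assert values == sorted(values, reverse=True)
        # Theta(1/r): r * nu_r tends to -ln(0.05)
        assert rs[-1] * values[-1] == pytest.approx(math.log(20), rel=1e-4)


class TestEmpiricalPdf:
    def test_equal_counts_single_bin(self):
        pdf = empirical_pdf(TranscriptCounts({"a": 5, "b": 5, "c": 5}), n_bins=20)
        assert pdf.density.sum() == pytest.approx(1.0)
        assert (pdf.density > 0).sum() == 1
        assert pdf.density.max() == pytest.approx(1.0)

    def test_two_level_counts(self):
        counts = TranscriptCounts({"a": 100, "b": 100, "c": 100, "d": 900})
        pdf = empirical_pdf(counts, n_bins=10)
        occupied = pdf.density[pdf.density > 0]
        assert sorted(occupied) == pytest.approx([0.25, 0.75])

    def test_single_transcript_degenerate(self):
        with pytest.raises(ValueError):
            empirical_pdf(TranscriptCounts({"a": 10}))

    def test_mass_sums_to_one(self, pilot_1m):
        pdf = empirical_pdf(pilot_1m)
        assert pdf.density.sum() == pytest.approx(1.0, abs=1e-9)


class TestFitPowerLaw:
    def test_exact_power_law_recovered_to_machine_precision(self):
        alpha = 2.0
        edges = np.geomspace(1e-6, 1e-2, 31)
        a = 1.0 - alpha
        mass = (edges[1:] ** a - edges[:-1] ** a) / a
        pdf = ExpressionPDF(bin_edges=edges, density=mass / mass.sum())
        fit_alpha, _ = fit_power_law(pdf, high_expr_threshold=1e-6)
        assert fit_alpha == pytest.approx(alpha, abs=1e-9)

    def test_synthetic_pilot_recovery(self, pilot_1m):
        pdf = empirical_pdf(pilot_1m)
        alpha, _ = fit_power_law(pdf)
        assert 1.9 <= alpha <= 2.1

    def test_threshold_above_all_bins(self, pilot_1m):
        pdf = empirical_pdf(pilot_1m)
        with pytest.raises(ValueError):
            fit_power_law(pdf, high_expr_threshold=1.0)


class TestCorrectPdf:
    def test_requires_fit(self, pilot_1m):
        with pytest.raises(ValueError):
            correct_pdf(empirical_pdf(pilot_1m))

    def test_deep_sample_is_noop(self):
        # reliable point far below every occupied bin: nothing to splice
        counts = TranscriptCounts(
            {f"t{i}": c for i, c in enumerate([10_000, 20_000, 40_000, 80_000, 850_000])}
        )
        pdf = empirical_pdf(counts, n_bins=10)
        fit_power_law(pdf, high_expr_threshold=pdf.bin_edges[0])
        corrected = correct_pdf(pdf)
        assert corrected.corrected
        np.testing.assert_allclose(corrected.density, pdf.density)
        np.testing.assert_allclose(corrected.bin_edges, pdf.bin_edges)

    def test_adds_mass_below_reliable_point(self, pilot_100k):
        pdf = empirical_pdf(pilot_100k)
        fit_power_law(pdf)
        corrected = correct_pdf(pdf)
        nu_r = corrected.nu_r
        below_corr = corrected.density[corrected.centers < nu_r].sum()
        below_unc = pdf.density[pdf.centers < nu_r].sum()
        assert below_corr > below_unc

    def test_shape_preserved_above_reliable_point(self, pilot_100k):
        # the splice keeps the empirical shape at and above nu_r: the
        # corrected masses there are one common renormalization factor
        # times the uncorrected ones
        pdf = empirical_pdf(pilot_100k)
        fit_power_law(pdf)
        corrected = correct_pdf(pdf)
        offset = corrected.bin_edges.size - pdf.bin_edges.size
        keep = (pdf.centers >= corrected.nu_r) & (pdf.density > 0)
        ratio = corrected.density[offset:][keep] / pdf.density[keep]
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_closer_to_truth_than_uncorrected(self, true_nu, pilot_1m):
        pdf = empirical_pdf(pilot_1m)
        fit_power_law(pdf)
        corrected = correct_pdf(pdf)
        edges = corrected.bin_edges
        truth = np.histogram(true_nu, bins=edges)[0] / true_nu.size
        outside = 1.0 - truth.sum()
        unc = np.zeros_like(corrected.density)
        unc[edges.size - pdf.bin_edges.size :] = pdf.density
        tv_corr = 0.5 * (np.abs(corrected.density - truth).sum() + outside)
        tv_unc = 0.5 * (np.abs(unc - truth).sum() + outside)
        assert tv_corr < tv_unc


class TestPredictDetection:
    def test_zero_depth(self, pilot_1m):
        pdf = empirical_pdf(pilot_1m)
        assert predict_detection(pdf, 0).expected_fraction == 0.0

    def test_point_mass_reduces_to_detection_prob(self):
        pdf = point_mass_pdf(1e-4)
        curve = predict_detection(pdf, 10**4)
        assert curve.expected_fraction == pytest.approx(detection_prob(1e-4, 10**4), rel=1e-6)

    def test_saturates_at_large_depth(self, pilot_1m):
        pdf = empirical_pdf(pilot_1m)
        assert predict_detection(pdf, 10**12).expected_fraction == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_depth(self, pilot_1m):
        pdf = empirical_pdf(pilot_1m)
        fractions = [
            predict_detection(pdf, d).expected_fraction for d in (0, 10, 10**3, 10**5, 10**7)
        ]
        assert fractions == sorted(fractions)


class TestRequiredDepth:
    def test_point_mass_closed_form(self):
        nu0, eps = 1e-4, 0.05
        pdf = point_mass_pdf(nu0)
        n = required_depth(pdf, eps)
        # center of the point-mass bin is nu0 exactly (geometric midpoint)
        assert n == math.ceil(math.log(eps) / math.log1p(-nu0))

    def test_tolerant_target_needs_little(self, pilot_1m):
        pdf = empirical_pdf(pilot_1m)
        assert required_depth(pdf, 0.999) <= required_depth(pdf, 0.5)

    def test_returned_depth_is_minimal(self, pilot_1m):
        pdf = empirical_pdf(pilot_1m)
        n = required_depth(pdf, 0.2)
        assert predict_detection(pdf, n).expected_fraction >= 0.8
        assert predict_detection(pdf, n - 1).expected_fraction < 0.8

    def test_invalid_epsilon(self, pilot_1m):
        with pytest.raises(ValueError):
            required_depth(empirical_pdf(pilot_1m), 0.0)


class TestCrossSamplePredict:
    def test_identical_to_direct_prediction(self, pilot_1m):
        pdf = empirical_pdf(pilot_1m)
        direct = predict_detection(pdf, 10**6)
        crossed = cross_sample_predict(pdf, 10**6)
        assert crossed.expected_fraction == direct.expected_fraction
        assert crossed.cross_sample and not direct.cross_sample

    def test_same_law_gives_consistent_curves(self, true_nu):
        from seqdesign.synth import sample_reads

        a = sample_reads(true_nu, 10**6, seed=101)
        b = sample_reads(true_nu, 10**6, seed=202)
        pdf_a, pdf_b = empirical_pdf(a), empirical_pdf(b)
        for pdf in (pdf_a, pdf_b):
            fit_power_law(pdf)
        ca, cb = correct_pdf(pdf_a), correct_pdf(pdf_b)
        for depth in (10**5, 10**6, 10**7):
            fa = cross_sample_predict(ca, depth).expected_fraction
            fb = predict_detection(cb, depth).expected_fraction
            assert fa == pytest.approx(fb, abs=0.05)

    def test_source_with_thinner_low_tail_over_predicts(self, true_nu):
        # a source law whose low-expression tail is thinner (steeper slope,
        # shares more equal) is optimistic about a heavier-tailed target
        from seqdesign.synth import ExpressionLaw, draw_expression, sample_reads

        shifted = draw_expression(ExpressionLaw(20_000, alpha=3.0, delta_d=1e-4, seed=7))
        src = sample_reads(shifted, 10**6, seed=8)
        tgt = sample_reads(true_nu, 10**6, seed=9)
        pdf_src, pdf_tgt = empirical_pdf(src), empirical_pdf(tgt)
        for pdf in (pdf_src, pdf_tgt):
            fit_power_law(pdf)
        c_src, c_tgt = correct_pdf(pdf_src), correct_pdf(pdf_tgt)
        depth = 10**6
        assert (
            cross_sample_predict(c_src, depth).expected_fraction
            > predict_detection(c_tgt, depth).expected_fraction
        )


def test_transcript_counts_validation():
    with pytest.raises(ValueError):
        TranscriptCounts({"a": 0})
    with pytest.raises(ValueError):
        TranscriptCounts({"a": 5}, total_reads=3)
    tc = TranscriptCounts({"a": 5, "b": 5}, total_reads=20)
    assert tc.mapped_reads == 10 and tc.total_reads == 20
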