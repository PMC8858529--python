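"""Estimators: moments, Pearson, CCC, LoA, sigma-hat, reference band."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from refband import (
    InvalidInputError,
    PairedSample,
    PopulationParams,
    ReferenceBand,
    UndefinedStatisticError,
    detect_outliers,
    limits_of_agreement,
    pearson_correlation,
    population_ccc,
    reference_band,
    sample_ccc,
    sigma_hat,
    summarize_pairs,
    t_quantile,
)
from conftest import random_sample


class TestPairedSample:
    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            PairedSample(np.arange(3.0), np.arange(4.0))

    def test_single_pair_rejected(self):
        with pytest.raises(InvalidInputError):
            PairedSample(np.array([1.0]), np.array([2.0]))

    def test_nan_rejected(self):
        with pytest.raises(InvalidInputError):
            PairedSample(np.array([1.0, np.nan]), np.array([1.0, 2.0]))

    def test_plane_coordinates(self):
        s = PairedSample.from_arrays([0.0, 2.0], [0.0, 4.0])
        np.testing.assert_allclose(s.differences, [0.0, 2.0])
        np.testing.assert_allclose(s.averages, [0.0, 3.0])


class TestSummarize:
    def test_identical_vectors(self):
        s = PairedSample.from_arrays([1, 2, 3, 4], [1, 2, 3, 4])
        est = summarize_pairs(s)
        assert est.dbar == 0.0
        assert est.sd_diff == 0.0
        assert est.ccc_hat == pytest.approx(1.0)
        assert est.cb_hat == pytest.approx(1.0)

    def test_hand_calculation(self):
        s = PairedSample.from_arrays([1, 2, 3], [2, 4, 6])
        est = summarize_pairs(s)
        assert est.dbar == pytest.approx(2.0)
        assert est.sd_diff == pytest.approx(1.0)
        assert est.mean1 == pytest.approx(2.0)
        assert est.mean2 == pytest.approx(4.0)

    def test_sd_diff_denominator_is_fixed(self):
        # sd of the differences keeps 1/(n-1) under both moment conventions
        s = PairedSample.from_arrays([1, 2, 3, 5], [2, 3, 5, 6])
        for denom in ("n", "n-1"):
            assert summarize_pairs(s, denom).sd_diff == pytest.approx(
                np.std(s.differences, ddof=1)
            )

    def test_sd_diff_consistent_with_moments(self):
        rng = np.random.default_rng(7)
        s = random_sample(rng, n=25)
        est = summarize_pairs(s, "n-1")
        expected = est.s1**2 + est.s2**2 - 2 * est.s12
        assert est.sd_diff**2 == pytest.approx(expected, rel=1e-10)

    def test_unknown_denominator(self):
        s = PairedSample.from_arrays([1, 2, 3], [2, 4, 6])
        with pytest.raises(InvalidInputError):
            summarize_pairs(s, "n-2")


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert pearson_correlation(
            PairedSample(x, 2 * x + 1)
        ) == pytest.approx(1.0)

    def test_perfect_negative(self):
        s = PairedSample.from_arrays([1, 2, 3], [3, 2, 1])
        assert pearson_correlation(s) == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        s = PairedSample.from_arrays([1, 1, 1], [1, 2, 3])
        with pytest.raises(UndefinedStatisticError):
            pearson_correlation(s)


class TestCCC:
    def test_shifted_vectors(self):
        # Lin's formula with 1/n variances: 2*1.25 / (1.25 + 1.25 + 1)
        s = PairedSample.from_arrays([1, 2, 3, 4], [2, 3, 4, 5])
        ccc, rho, cb = sample_ccc(s)
        assert rho == pytest.approx(1.0)
        assert ccc == pytest.approx(5.0 / 7.0)
        assert cb == pytest.approx(5.0 / 7.0)

    def test_pefr_values(self, pefr):
        ccc, rho, cb = sample_ccc(pefr)
        assert ccc == pytest.approx(0.943, abs=5e-4)
        assert rho == pytest.approx(0.943, abs=5e-4)
        assert cb == pytest.approx(0.999, abs=5e-4)

    def test_population_scenario_values(self):
        rho_c, cb = population_ccc(PopulationParams(1, 1, 1, 1, 0.75))
        assert cb == pytest.approx(1.0)
        assert rho_c == pytest.approx(0.75)
        rho_c, cb = population_ccc(PopulationParams(1, 1.5, 1, 1.2, 0.6725))
        assert cb == pytest.approx(0.8922, abs=1e-4)
        assert rho_c == pytest.approx(0.6, abs=1e-3)

    def test_population_zero_correlation(self):
        rho_c, _ = population_ccc(PopulationParams(0, 3, 1, 2, 0.0))
        assert rho_c == 0.0

    def test_invalid_sigma(self):
        with pytest.raises(InvalidInputError):
            PopulationParams(0, 0, -1.0, 1.0, 0.5)


class TestLimitsOfAgreement:
    def test_constant_differences(self):
        s = PairedSample.from_arrays([1, 2, 3], [4, 5, 6])
        loa = limits_of_agreement(s)
        assert loa.dbar == pytest.approx(3.0)
        assert loa.half_width == 0.0

    def test_symmetric_differences(self):
        # S_d = 1 and t_{2,0.025} = 4.3027 from standard tables
        s = PairedSample.from_arrays([0, 0, 0], [-1, 0, 1])
        loa = limits_of_agreement(s, alpha=0.05)
        assert loa.dbar == pytest.approx(0.0)
        assert loa.half_width == pytest.approx(4.3027, abs=2e-4)
        assert loa.lower == -loa.half_width
        assert loa.upper == loa.half_width

    def test_pefr_limits(self, pefr):
        loa = limits_of_agreement(pefr)
        assert loa.dbar == pytest.approx(-2.12, abs=5e-3)
        assert loa.half_width == pytest.approx(82.18, abs=5e-3)


class TestTQuantile:
    @pytest.mark.parametrize(
        "df,alpha,expected", [(16, 0.05, 2.1199), (2, 0.05, 4.3027)]
    )
    def test_table_values(self, df, alpha, expected):
        assert t_quantile(df, alpha) == pytest.approx(expected, abs=2e-4)

    def test_decreasing_in_df(self):
        qs = [t_quantile(df, 0.05) for df in (1, 2, 5, 10, 50, 500)]
        assert all(a > b for a, b in zip(qs, qs[1:]))

    def test_invalid_args(self):
        with pytest.raises(InvalidInputError):
            t_quantile(0, 0.05)
        with pytest.raises(InvalidInputError):
            t_quantile(5, 1.5)


class TestSigmaHat:
    def test_closed_form(self):
        assert sigma_hat(math.sqrt(2), 0.5, 1, 1) == pytest.approx(
            math.sqrt(2)
        )

    def test_degenerate_fallback(self):
        assert sigma_hat(0.0, 1.0, 3.0, 3.0) == pytest.approx(3.0)

    def test_scenario_magnitude(self):
        # S_d and rho-hat of a near-threshold draw give sigma-hat ~ 1.058
        assert sigma_hat(0.713, 0.773, 1, 1) == pytest.approx(1.058, abs=2e-3)

    def test_rho_out_of_range(self):
        with pytest.raises(InvalidInputError):
            sigma_hat(1.0, 1.5, 1, 1)


class TestReferenceBand:
    def test_pefr_band(self, pefr):
        band = reference_band(pefr)
        assert band.half_width == pytest.approx(172.53, abs=5e-2)
        assert band.center == 0.0
        assert band.lower == -band.upper

    def test_band_equals_loa_when_rho_at_threshold(self):
        rng = np.random.default_rng(3)
        s = random_sample(rng, n=40, rho=0.6)
        rho = pearson_correlation(s)
        band = reference_band(s, rho_L=rho)
        loa = limits_of_agreement(s)
        assert band.half_width == pytest.approx(loa.half_width, rel=1e-12)

    def test_rho_l_out_of_range(self, pefr):
        with pytest.raises(InvalidInputError):
            reference_band(pefr, rho_L=1.2)

    def test_negative_correlation_warns(self):
        s = PairedSample.from_arrays([1, 2, 3, 4], [5, 3, 4, 1])
        with pytest.warns(UserWarning, match="negative correlation"):
            reference_band(s)

    @pytest.mark.parametrize("seed", range(6))
    def test_formula_equivalence(self, seed):
        """t*S_d*sqrt((1-rho_L)/(1-rho)) == t*sigma_hat*sqrt(2(1-rho_L))."""
        rng = np.random.default_rng(seed)
        s = random_sample(rng, n=20, rho=rng.uniform(-0.5, 0.95))
        band = reference_band(s, rho_L=0.75)
        tq = t_quantile(s.n - 1, 0.05)
        sd = float(s.differences.std(ddof=1))
        rho = pearson_correlation(s)
        sig = sd / math.sqrt(2 * (1 - rho))
        assert band.half_width == pytest.approx(
            tq * sig * math.sqrt(2 * 0.25), rel=1e-10
        )

    @pytest.mark.parametrize("rho_L", [0.3, 0.75, 0.9])
    @pytest.mark.parametrize("seed", range(5))
    def test_order_equivalences(self, rho_L, seed):
        """rho vs rho_L orders exactly as omega_RB vs omega."""
        rng = np.random.default_rng(100 + seed)
        s = random_sample(rng, n=25, rho=rng.uniform(0.0, 0.98))
        rho = pearson_correlation(s)
        band = reference_band(s, rho_L=rho_L)
        loa = limits_of_agreement(s)
        if rho > rho_L:
            assert band.half_width > loa.half_width
        elif rho < rho_L:
            assert band.half_width < loa.half_width
        else:
            assert band.half_width == pytest.approx(loa.half_width)


class TestOutliers:
    def test_strict_boundary(self):
        s = PairedSample.from_arrays([0, 0, 0], [0.2, -1.6, 1.5])
        band = ReferenceBand(half_width=1.5, rho_L=0.75, alpha=0.05, df=2)
        report = detect_outliers(s, band)
        assert report.outlier_indices == (1,)
        assert report.pct_outliers == pytest.approx(100 / 3)

    def test_no_differences_no_outliers(self):
        s = PairedSample.from_arrays([1, 2, 3], [1, 2, 3])
        band = ReferenceBand(half_width=0.0, rho_L=0.75, alpha=0.05, df=2)
        assert detect_outliers(s, band).n_outliers == 0

    def test_pefr_all_inside(self, pefr):
        band = reference_band(pefr)
        assert detect_outliers(pefr, band).n_outliers == 0


@st.composite
def paired_samples(draw):
    n = draw(st.integers(min_value=5, max_value=40))
    seed = draw(st.integers(min_value=0, max_value=2**31 - 1))
    rho = draw(st.floats(min_value=-0.9, max_value=0.98))
    rng = np.random.default_rng(seed)
    return random_sample(rng, n=n, rho=rho)


class TestProperties:
    @given(paired_samples(), st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=60, deadline=None)
    def test_scale_equivariance(self, sample, c):
        """Rescaling both columns scales widths and fixes scaled indices."""
        scaled = PairedSample(c * sample.x1, c * sample.x2)
        e0, e1 = summarize_pairs(sample), summarize_pairs(scaled)
        assert e1.dbar == pytest.approx(c * e0.dbar, rel=1e-9, abs=1e-12)
        assert e1.sd_diff == pytest.approx(c * e0.sd_diff, rel=1e-9)
        assert e1.rho_hat == pytest.approx(e0.rho_hat, rel=1e-9)
        assert e1.ccc_hat == pytest.approx(e0.ccc_hat, rel=1e-9)
        b0, b1 = reference_band(sample), reference_band(scaled)
        assert b1.half_width == pytest.approx(c * b0.half_width, rel=1e-9)
        assert (
            detect_outliers(scaled, b1).outlier_indices
            == detect_outliers(sample, b0).outlier_indices
        )

    @given(paired_samples(), st.floats(min_value=-100, max_value=100))
    @settings(max_examples=60, deadline=None)
    def test_translation_invariance(self, sample, shift):
        """A common shift moves only the means."""
        moved = PairedSample(sample.x1 + shift, sample.x2 + shift)
        e0, e1 = summarize_pairs(sample), summarize_pairs(moved)
        assert e1.mean1 == pytest.approx(e0.mean1 + shift, abs=1e-8)
        assert e1.dbar == pytest.approx(e0.dbar, abs=1e-8)
        assert e1.sd_diff == pytest.approx(e0.sd_diff, rel=1e-9)
        assert e1.rho_hat == pytest.approx(e0.rho_hat, rel=1e-9)

    @given(paired_samples())
    @settings(max_examples=100, deadline=None)
    def test_index_bounds(self, sample):
        """0 < C_b <= 1 and |ccc| <= |rho| on every valid sample."""
        ccc, rho, cb = sample_ccc(sample)
        assert 0.0 < cb <= 1.0 + 1e-12
        assert abs(ccc) <= abs(rho) + 1e-12
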