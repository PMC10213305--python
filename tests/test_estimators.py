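"""IVW, MR-Egger and weighted-median estimators against printed and oracle values."""

import numpy as np
import pytest

from tsmr.estimators import (
    Z_95,
    egger,
    ivw,
    wald_ratio,
    weighted_median,
    _weighted_median_point,
)
from tsmr.harmonize import HarmonizedSet, HarmonizedSnp, orient_positive_exposure


def _set(rows):
    return HarmonizedSet(
        [HarmonizedSnp(f"rs{i}", *row) for i, row in enumerate(rows)]
    )


class TestWaldRatio:
    def test_single_instrument_ratio_and_first_order_se(self, chinese_set):
        est = wald_ratio(chinese_set["rs56129017"])
        assert est.ratio == pytest.approx(-0.122 / 0.131, abs=1e-4)
        assert est.ratio == pytest.approx(-0.9313, abs=5e-4)
        assert est.se_ratio == pytest.approx(0.088 / 0.131, abs=1e-4)
        assert est.se_ratio == pytest.approx(0.6718, abs=5e-4)
        assert est.weight == pytest.approx(1.0 / est.se_ratio**2)

    def test_zero_outcome_effect(self):
        est = wald_ratio(HarmonizedSnp("rs1", 0.1, 0.01, 0.0, 0.05))
        assert est.ratio == 0.0
        assert est.se_ratio == pytest.approx(0.5)

    def test_null_instrument_errors(self):
        with pytest.raises(ValueError, match="null instrument"):
            wald_ratio(HarmonizedSnp("rs1", 0.0, 0.01, 0.1, 0.05))


class TestIVW:
    def test_chinese_cohort_matches_published_row(self, chinese_set):
        est = ivw(chinese_set)
        assert est.or_ == pytest.approx(0.510, abs=0.02)
        assert est.ci_low == pytest.approx(0.149, abs=0.03)
        assert est.ci_high == pytest.approx(1.749, abs=0.03)
        assert est.pval == pytest.approx(0.284, abs=0.015)
        assert est.n_snp == 5

    def test_japanese_cohort_matches_published_row(self, japanese_set):
        est = ivw(japanese_set)
        assert est.or_ == pytest.approx(1.170, abs=0.02)
        assert est.ci_low == pytest.approx(0.790, abs=0.03)
        assert est.ci_high == pytest.approx(1.734, abs=0.03)
        assert est.pval == pytest.approx(0.434, abs=0.015)

    def test_single_snp_fixed_reduces_to_wald_ratio(self):
        snp = HarmonizedSnp("rs1", 0.1, 0.01, 0.05, 0.04)
        est = ivw(HarmonizedSet([snp]), model="fixed")
        ratio = wald_ratio(snp)
        assert est.beta == pytest.approx(ratio.ratio, rel=1e-12)
        assert est.se == pytest.approx(ratio.se_ratio, rel=1e-12)
        with pytest.raises(ValueError, match="at least 2"):
            ivw(HarmonizedSet([snp]), model="multiplicative_random")

    def test_weight_formula_equals_regression_path(self, chinese_set, japanese_set):
        """IVW must equal the zero-intercept WLS slope (independent route)."""
        sm = pytest.importorskip("statsmodels.api")
        for hset in (chinese_set, japanese_set):
            bx, _, by, sy = hset.arrays()
            fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
            est = ivw(hset, model="fixed")
            assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
            # multiplicative dispersion equals the WLS residual scale
            mre = ivw(hset)
            assert mre.extra["sigma2"] == pytest.approx(fit.scale, rel=1e-10)

    def test_invariant_under_reordering_and_orientation(self, chinese_tables):
        from tsmr.harmonize import harmonize

        hset, _ = harmonize(*chinese_tables)
        oriented = orient_positive_exposure(hset)
        shuffled = hset.replaced(list(hset)[::-1])
        reference = ivw(oriented).beta
        assert ivw(hset).beta == pytest.approx(reference, rel=1e-12)
        assert ivw(shuffled).beta == pytest.approx(reference, rel=1e-12)

    def test_fixed_se_below_random_se_iff_overdispersed(self, chinese_set, japanese_set):
        # Chinese ratios overdisperse (sigma2 > 1), Japanese underdisperse
        ch_fixed, ch_mre = ivw(chinese_set, "fixed"), ivw(chinese_set)
        jp_fixed, jp_mre = ivw(japanese_set, "fixed"), ivw(japanese_set)
        assert ch_mre.extra["sigma2"] > 1 and ch_fixed.se < ch_mre.se
        assert jp_mre.extra["sigma2"] < 1 and jp_fixed.se > jp_mre.se


class TestEgger:
    def test_chinese_cohort_matches_published_fit(self, chinese_set):
        est = egger(chinese_set)
        assert est.or_ == pytest.approx(0.223, abs=0.02)
        assert est.pval == pytest.approx(0.348, abs=0.015)
        block = est.extra["intercept"]
        assert block.intercept == pytest.approx(0.069, abs=0.005)
        assert block.se_intercept == pytest.approx(0.098, abs=0.005)
        assert block.pval_intercept == pytest.approx(0.531, abs=0.015)

    def test_japanese_cohort_matches_published_fit(self, japanese_set):
        est = egger(japanese_set)
        assert est.or_ == pytest.approx(1.085, abs=0.03)
        assert est.pval == pytest.approx(0.890, abs=0.015)
        block = est.extra["intercept"]
        assert block.intercept == pytest.approx(0.006, abs=0.005)
        assert block.se_intercept == pytest.approx(0.036, abs=0.005)
        assert block.pval_intercept == pytest.approx(0.882, abs=0.015)

    def test_agrees_with_wls_oracle(self, chinese_set):
        sm = pytest.importorskip("statsmodels.api")
        bx, _, by, sy = chinese_set.arrays()
        design = np.column_stack([np.ones_like(bx), bx])
        fit = sm.WLS(by, design, weights=1.0 / sy**2).fit()
        est = egger(chinese_set)
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.se == pytest.approx(fit.bse[1], abs=1e-10)
        assert est.extra["intercept"].intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert est.pval == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_exact_recovery_on_noise_free_linear_data(self):
        theta = 0.37
        bx = np.array([0.03, 0.05, 0.08, 0.11, 0.13])
        rows = [(x, 0.005, theta * x, 0.05) for x in bx]
        est = egger(_set(rows))
        assert est.beta == pytest.approx(theta, abs=1e-12)
        assert est.extra["intercept"].intercept == pytest.approx(0.0, abs=1e-12)

    def test_requires_three_instruments_and_orientation(self):
        with pytest.raises(ValueError, match="insufficient"):
            egger(_set([(0.1, 0.01, 0.1, 0.05), (0.2, 0.01, 0.1, 0.05)]))
        with pytest.raises(ValueError, match="orient"):
            egger(_set([(0.1, 0.01, 0.1, 0.05), (-0.2, 0.01, 0.1, 0.05),
                        (0.3, 0.01, 0.1, 0.05)]))


class TestWeightedMedian:
    def test_chinese_and_japanese_point_estimates(self, chinese_set, japanese_set):
        assert weighted_median(chinese_set, seed=0).or_ == pytest.approx(0.385, abs=0.02)
        assert weighted_median(japanese_set, seed=0).or_ == pytest.approx(1.095, abs=0.02)

    def test_equal_weight_interpolation_picks_middle_ratio(self):
        # three equally weighted ratios (1, 2, 9): the 50% point is the middle
        rows = [(0.1, 0.01, 0.1 * r, 0.05) for r in (1.0, 2.0, 9.0)]
        est = weighted_median(_set(rows), n_boot=200, seed=1)
        assert est.beta == pytest.approx(2.0, rel=1e-12)

    def test_equal_weights_match_unweighted_interpolated_median(self):
        rng = np.random.default_rng(7)
        ratios = rng.normal(size=8)
        point = _weighted_median_point(ratios, np.ones(8))
        s = (np.arange(8) + 0.5) / 8
        assert point == pytest.approx(np.interp(0.5, s, np.sort(ratios)), rel=1e-12)

    def test_dominant_weight_converges_to_that_ratio(self):
        ratios = np.array([-1.0, 0.5, 3.0])
        weights = np.array([1e-9, 1e12, 1e-9])
        assert _weighted_median_point(ratios, weights) == pytest.approx(0.5, abs=1e-6)

    def test_bootstrap_reproducible_for_fixed_seed(self, chinese_set):
        a = weighted_median(chinese_set, n_boot=500, seed=42)
        b = weighted_median(chinese_set, n_boot=500, seed=42)
        assert a.se == b.se and a.pval == b.pval
        c = weighted_median(chinese_set, n_boot=500, seed=43)
        assert c.se != a.se

    def test_small_bootstrap_warns(self, chinese_set):
        with pytest.warns(UserWarning, match="n_boot"):
            weighted_median(chinese_set, n_boot=50, seed=1)


def test_ci_bounds_bracket_or():
    est = ivw(
        _set([(0.1, 0.01, 0.05, 0.05), (0.2, 0.01, 0.01, 0.04), (0.15, 0.01, 0.02, 0.06)])
    )
    assert est.ci_low == pytest.approx(np.exp(est.beta - Z_95 * est.se), rel=1e-12)
    assert est.ci_high == pytest.approx(np.exp(est.beta + Z_95 * est.se), rel=1e-12)
    assert est.ci_low < est.or_ < est.ci_high
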