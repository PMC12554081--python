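"""Unit and property tests for the effect-size metrics and conversions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from effectkit import (
    ContingencyTable,
    TwoGroupSummary,
    cohens_d,
    d_to_r,
    hedges_g,
    odds_ratio,
    pearson_r,
    point_biserial,
    r_to_d,
    risk_ratio,
    semipartial_r,
    significance_tests,
    t_test,
)
from effectkit.exceptions import (
    InvalidInputError,
    UndefinedCorrelationError,
    ZeroCellError,
)


class TestCohensD:
    @pytest.mark.parametrize(
        "summary, expected",
        [
            (TwoGroupSummary(12, 2, 30, 10, 2, 30), 1.0),
            (TwoGroupSummary(7.3, 1.4, 12, 7.3, 2.1, 15), 0.0),
            # heights example: back-solved common sd gives d = 1.03
            (TwoGroupSummary(175.3, 13.5922, 5000, 161.3, 13.5922, 5000), 1.03),
        ],
    )
    def test_worked_examples(self, summary, expected):
        assert cohens_d(summary).value == pytest.approx(expected, abs=5e-4)

    def test_invalid_sd_rejected(self):
        with pytest.raises(InvalidInputError):
            TwoGroupSummary(1.0, 0.0, 10, 0.0, 1.0, 10)

    def test_se_formula(self):
        est = cohens_d(TwoGroupSummary(12, 2, 30, 10, 2, 30))
        n1 = n2 = 30
        expected_se = math.sqrt((n1 + n2) / (n1 * n2) + est.value**2 / (2 * (n1 + n2)))
        assert est.se == pytest.approx(expected_se, rel=1e-12)
        assert est.ci_low < est.value < est.ci_high

    def test_weighted_pooling_matches_classic_formula(self):
        s = TwoGroupSummary(10, 2, 10, 8, 3, 40)
        classic = math.sqrt((9 * 4 + 39 * 9) / 48)
        est = cohens_d(s, weighted_pooling=True)
        assert est.value == pytest.approx(2 / classic, rel=1e-12)

    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.01, 100),
        seed=st.integers(0, 1000),
    )
    def test_shift_and_scale_invariance(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        g1 = rng.normal(0.4, 1.1, 20)
        g2 = rng.normal(0.0, 0.9, 25)
        base = cohens_d(TwoGroupSummary.from_samples(g1, g2)).value
        moved = cohens_d(
            TwoGroupSummary.from_samples(g1 * scale + shift, g2 * scale + shift)
        ).value
        assert moved == pytest.approx(base, rel=1e-9)


class TestHedgesG:
    def test_correction_factor(self):
        d_est = cohens_d(TwoGroupSummary(12, 2, 30, 10, 2, 30))
        g = hedges_g(d_est, 30, 30)
        assert g.value == pytest.approx(1.0 * (1 - 3 / 231), rel=1e-12)
        assert g.metric == "g"

    def test_zero_effect_stays_zero(self):
        d_est = cohens_d(TwoGroupSummary(5, 1, 10, 5, 1, 10))
        assert hedges_g(d_est, 10, 10).value == 0.0

    def test_correction_vanishes_at_large_n(self):
        d_est = cohens_d(TwoGroupSummary(12, 2, 500000, 10, 2, 500000))
        g = hedges_g(d_est, 500000, 500000)
        assert g.value == pytest.approx(d_est.value, abs=1e-5)

    def test_tiny_sample_rejected(self):
        d_est = cohens_d(TwoGroupSummary(12, 2, 30, 10, 2, 30))
        with pytest.raises(InvalidInputError):
            hedges_g(d_est, 1, 1)


class TestConversions:
    @pytest.mark.parametrize(
        "d, expected",
        [(0.86, 0.3950), (0.0, 0.0), (2.0, 0.70711)],
    )
    def test_d_to_r(self, d, expected):
        assert d_to_r(d) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize(
        "r, expected",
        [(0.04, 0.08006), (0.20, 0.40825), (0.5, 1.15470), (0.0, 0.0)],
    )
    def test_r_to_d(self, r, expected):
        assert r_to_d(r) == pytest.approx(expected, abs=5e-5)

    def test_r_to_d_rejects_unit_correlation(self):
        with pytest.raises(InvalidInputError):
            r_to_d(1.0)

    @given(st.floats(-5, 5))
    def test_round_trip(self, d):
        assert r_to_d(d_to_r(d)) == pytest.approx(d, abs=1e-12)

    @given(st.floats(-3, 3))
    def test_d_to_r_stays_in_open_interval(self, d):
        assert -1 < d_to_r(d) < 1


class TestCorrelations:
    def test_perfect_and_null_correlation(self, rng):
        x = rng.normal(size=50)
        assert pearson_r(x, x).value == pytest.approx(1.0)
        # orthogonal construction: y has zero sample covariance with x
        y = rng.normal(size=50)
        y = y - x * np.dot(x - x.mean(), y - y.mean()) / np.dot(x - x.mean(), x - x.mean())
        assert pearson_r(x, y).value == pytest.approx(0.0, abs=1e-10)

    def test_r_squared_from_r(self):
        # r = 0.5 corresponds to 25% shared variance
        assert 0.5**2 == pytest.approx(0.25)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_fisher_ci_brackets_value(self, rng):
        x = rng.normal(size=100)
        y = 0.5 * x + rng.normal(size=100)
        est = pearson_r(x, y)
        assert est.ci_low < est.value < est.ci_high
        assert est.se == pytest.approx(1 / math.sqrt(97))

    def test_point_biserial_equals_pearson_on_dummy(self, rng):
        values = rng.normal(size=60)
        labels = np.repeat(["a", "b"], 30)
        rpb = point_biserial(values, labels)
        dummy = (labels == "b").astype(float)
        assert rpb.value == pearson_r(values, dummy).value  # bit-for-bit

    def test_point_biserial_zero_for_equal_means(self):
        values = np.concatenate([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        labels = np.repeat([0, 1], 3)
        assert point_biserial(values, labels).value == pytest.approx(0.0, abs=1e-12)

    def test_point_biserial_single_group_rejected(self):
        with pytest.raises(InvalidInputError):
            point_biserial([1.0, 2.0, 3.0], ["a", "a", "a"])

    def test_point_biserial_recovers_converted_d(self, rng):
        # simulated at population d = 0.86 with equal n: r_pb ~ d_to_r(sample d)
        n = 4000
        g1 = rng.normal(0.86, 1.0, n)
        g2 = rng.normal(0.0, 1.0, n)
        values = np.concatenate([g1, g2])
        labels = np.repeat([1, 0], n)
        rpb = abs(point_biserial(values, labels).value)
        d_hat = cohens_d(TwoGroupSummary.from_samples(g1, g2)).value
        assert rpb == pytest.approx(abs(d_to_r(d_hat)), abs=5e-3)
        assert rpb == pytest.approx(0.395, abs=0.03)


class TestSemipartialR:
    @pytest.mark.parametrize(
        "t, df, r2, expected",
        [(0.0, 50, 0.3, 0.0), (3.0, 100, 0.19, 0.27), (-3.0, 100, 0.19, -0.27)],
    )
    def test_identity(self, t, df, r2, expected):
        assert semipartial_r(t, df, r2).value == pytest.approx(expected, abs=1e-12)

    def test_single_predictor_reduces_to_pearson(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=200)
        y = 0.4 * x + rng.normal(size=200)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        rsp = semipartial_r(float(fit.tvalues[1]), float(fit.df_resid), float(fit.rsquared))
        assert rsp.value == pytest.approx(pearson_r(x, y).value, abs=1e-10)

    def test_full_r2_rejected(self):
        with pytest.raises(InvalidInputError):
            semipartial_r(1.0, 10, 1.0)


class TestContingencyRatios:
    def test_odds_ratio_examples(self):
        assert odds_ratio(ContingencyTable(10, 10, 10, 10)).value == 1.0
        assert odds_ratio(ContingencyTable(20, 10, 10, 20)).value == 4.0

    def test_odds_ratio_row_swap_inverts(self):
        t = ContingencyTable(17, 8, 5, 23)
        assert odds_ratio(ContingencyTable(t.c, t.d, t.a, t.b)).value == pytest.approx(
            1 / odds_ratio(t).value, rel=1e-12
        )

    def test_zero_cell_errors_name_the_cell(self):
        with pytest.raises(ZeroCellError) as exc:
            odds_ratio(ContingencyTable(5, 0, 3, 7))
        assert exc.value.cell == "b"
        # continuity correction rescues it
        est = odds_ratio(ContingencyTable(5, 0, 3, 7), continuity_correction=True)
        assert est.value > 0

    def test_risk_ratio_examples(self):
        assert risk_ratio(ContingencyTable(10, 90, 5, 95)).value == pytest.approx(2.0)
        assert risk_ratio(ContingencyTable(5, 45, 10, 90)).value == pytest.approx(1.0)

    def test_log_scale_ci_brackets(self):
        est = risk_ratio(ContingencyTable(10, 90, 5, 95))
        assert est.ci_low < est.value < est.ci_high
        assert est.ci_low > 0

    @given(
        a=st.integers(1, 40), b=st.integers(60, 200),
        c=st.integers(1, 40), d=st.integers(60, 200),
    )
    def test_or_at_least_rr_for_rare_positive_association(self, a, b, c, d):
        # event probability < 0.5 in both arms; restrict to positive association
        t = ContingencyTable(a, b, c, d)
        if a / (a + b) <= c / (c + d):
            return
        assert odds_ratio(t).value >= risk_ratio(t).value - 1e-12


class TestSignificanceFormulations:
    def test_identical_groups_give_t0_p1(self):
        res = significance_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        for r in res:
            assert r.statistic == pytest.approx(0.0, abs=1e-12)
            assert r.p_value == pytest.approx(1.0, abs=1e-12)

    def test_three_formulations_agree(self, two_group_sample):
        res = significance_tests(*two_group_sample)
        stats_ = [r.statistic for r in res]
        ps = [r.p_value for r in res]
        assert max(stats_) - min(stats_) < 1e-10
        assert max(ps) - min(ps) < 1e-10
        assert {r.formulation for r in res} == {"mean_difference", "slope", "correlation"}

    def test_correlation_formulation_closed_form(self):
        # r = 0.40 observed with 60 total: t = 0.40 * sqrt(58 / 0.84)
        t = 0.40 * math.sqrt(58 / (1 - 0.16))
        assert t == pytest.approx(3.3238, abs=2e-4)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(InvalidInputError):
            significance_tests([2.0, 2.0], [2.0, 2.0])

    def test_welch_option_differs_under_variance_heterogeneity(self, rng):
        g1 = rng.normal(0, 0.5, 20)
        g2 = rng.normal(0, 3.0, 80)
        pooled = t_test(g1, g2, equal_var=True)
        welch = t_test(g1, g2, equal_var=False)
        assert welch.df != pooled.df
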