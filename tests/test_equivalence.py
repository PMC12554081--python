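"""Equivalence testing, verdict logic, and the TOST cross-check."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from effectkit import (
    SESOI,
    equivalence_test,
    equivalence_verdict,
    normative_comparison,
    tost_crosscheck,
)
from effectkit.exceptions import InvalidInputError, UnsupportedCombinationError

BAND = SESOI.symmetric_about_zero(0.1)


def oracle_p(b, s, delta):
    """Hand-computed normal-probability arithmetic, independent of the
    implementation's code path."""
    return stats.norm.cdf((abs(b) - delta) / s) - stats.norm.cdf((-abs(b) - delta) / s)


class TestPValue:
    def test_worked_example(self):
        res = equivalence_test(0.02, 0.04, BAND)
        expected = stats.norm.cdf(-2) - stats.norm.cdf(-3)
        assert res.p_equivalence == pytest.approx(expected, abs=1e-12)
        assert res.p_equivalence == pytest.approx(0.02140, abs=5e-6)
        assert res.p_equivalence <= 0.05  # reject non-equivalence
        assert res.verdict == "equivalent"

    def test_zero_estimate_gives_zero_p(self):
        assert equivalence_test(0.0, 0.3, BAND).p_equivalence == 0.0

    def test_far_outside_saturates(self):
        res = equivalence_test(1.0, 0.05, BAND)
        assert res.p_equivalence == pytest.approx(1.0, abs=1e-6)
        assert res.verdict == "meaningful"

    @given(st.floats(-0.5, 0.5))
    def test_sign_invariance(self, b):
        p1 = equivalence_test(b, 0.05, BAND).p_equivalence
        p2 = equivalence_test(-b, 0.05, BAND).p_equivalence
        assert p1 == p2

    def test_monotone_in_estimate_and_delta(self):
        ps = [equivalence_test(b, 0.05, BAND).p_equivalence
              for b in np.linspace(0.01, 0.5, 25)]
        assert all(a < b for a, b in zip(ps, ps[1:]))
        pds = [equivalence_test(0.05, 0.05, SESOI.symmetric_about_zero(d)).p_equivalence
               for d in np.linspace(0.02, 0.5, 25)]
        assert all(a > b for a, b in zip(pds, pds[1:]))

    def test_asymmetric_interval_rejected_for_p(self):
        with pytest.raises(UnsupportedCombinationError):
            equivalence_test(0.0, 0.1, SESOI(lower=-0.05, upper=0.2))

    def test_bad_se_rejected(self):
        with pytest.raises(InvalidInputError):
            equivalence_test(0.0, 0.0, BAND)


class TestVerdict:
    @pytest.mark.parametrize(
        "ci, expected",
        [
            ((-0.05, 0.03), "equivalent"),
            ((-0.25, -0.12), "meaningful"),
            ((-0.15, -0.10), "inconclusive"),  # endpoint touching a bound
            ((-0.15, 0.05), "inconclusive"),
        ],
    )
    def test_three_way_rule(self, ci, expected):
        lo, hi = ci
        assert equivalence_verdict((lo + hi) / 2, lo, hi, BAND) == expected

    def test_verdict_consistency_invariants(self):
        # equivalent => CI inside the band; meaningful => outside one side
        rng = np.random.default_rng(11)
        for _ in range(500):
            b = rng.uniform(-0.4, 0.4)
            s = rng.uniform(0.005, 0.2)
            res = equivalence_test(b, s, BAND)
            if res.verdict == "equivalent":
                assert BAND.lower < res.ci_low and res.ci_high < BAND.upper
            elif res.verdict == "meaningful":
                assert res.ci_high < BAND.lower or res.ci_low > BAND.upper


class TestTOST:
    @pytest.mark.parametrize(
        "b, s, expected",
        [
            (0.0, 0.01, 0.0),
            (0.1, 0.05, 0.5),  # estimate exactly at the bound
            (0.02, 0.04, 0.02275),
        ],
    )
    def test_worked_examples(self, b, s, expected):
        assert tost_crosscheck(b, s, BAND) == pytest.approx(expected, abs=2e-5)

    def test_decision_agreement_away_from_boundary(self):
        """Normal-theory p and TOST agree at alpha=.05 whenever the estimate
        is clearly inside or clearly outside the interval (3 SEs clear of a
        bound).

        Inside that margin the two p-values can straddle alpha, because the
        normal-theory p subtracts the far-tail term Phi(-(|b|+delta)/s) from
        the one-sided TOST p; those cases are counted and reported, not
        asserted.
        """
        rng = np.random.default_rng(5)
        boundary_disagreements = 0
        checked = 0
        for _ in range(10_000):
            b = rng.uniform(-0.4, 0.4)
            s = rng.uniform(0.005, 0.15)
            delta = rng.uniform(0.05, 0.3)
            band = SESOI.symmetric_about_zero(delta)
            p_eq = equivalence_test(b, s, band).p_equivalence
            p_tost = tost_crosscheck(b, s, band)
            clearly_decided = abs(abs(b) - delta) > 3 * s
            if not clearly_decided:
                if (p_eq <= 0.05) != (p_tost <= 0.05):
                    boundary_disagreements += 1
                continue
            checked += 1
            assert (p_eq <= 0.05) == (p_tost <= 0.05), (b, s, delta, p_eq, p_tost)
        assert checked > 2000
        print(f"boundary-band decision disagreements: {boundary_disagreements}")

    def test_tost_always_upper_bounds_normal_theory_p(self):
        rng = np.random.default_rng(8)
        for _ in range(500):
            b = rng.uniform(-0.5, 0.5)
            s = rng.uniform(0.005, 0.3)
            band = SESOI.symmetric_about_zero(rng.uniform(0.02, 0.3))
            assert (equivalence_test(b, s, band).p_equivalence
                    <= tost_crosscheck(b, s, band) + 1e-15)


class TestRejectionRates:
    def test_equivalence_rejection_rises_as_precision_improves(self):
        """True effect 0: P(declared equivalent) -> 1 as SE shrinks;
        true effect 0.15 (outside the band): it -> 0."""
        rng = np.random.default_rng(42)
        reps = 2000
        for true_effect, increasing in [(0.0, True), (0.15, False)]:
            rates = []
            for se in (0.2, 0.04, 0.01):
                draws = rng.normal(true_effect, se, reps)
                rej = np.mean([
                    equivalence_test(b, se, BAND).p_equivalence <= 0.05
                    for b in draws
                ])
                rates.append(rej)
            if increasing:
                assert rates[0] < rates[-1] and rates[-1] > 0.99
            else:
                assert rates[0] > rates[-1] and rates[-1] < 0.01


class TestNormativeComparison:
    def test_bitwise_wrapper(self):
        a = normative_comparison(0.01, 0.02, BAND)
        b = equivalence_test(0.01, 0.02, BAND)
        assert a == b

    def test_returned_to_normative_levels(self):
        res = normative_comparison(0.01, 0.02, BAND)
        expected = stats.norm.cdf(-4.5) - stats.norm.cdf(-5.5)
        assert res.p_equivalence == pytest.approx(expected, rel=1e-9)
        assert res.verdict == "equivalent"

    def test_far_from_normative(self):
        assert normative_comparison(0.5, 0.05, BAND).verdict == "meaningful"
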