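"""Equivalence testing against a smallest effect size of interest (SESOI).

The SESOI is a pre-declared interval, typically symmetric about zero (e.g.
a standardized slope of +/-0.10), below which an effect is considered
practically negligible.  The test reverses the usual null-hypothesis logic:
the null is that the effect lies *outside* the interval, so rejection is
positive evidence of negligibility.

The p-value for a symmetric interval of half-width delta around zero is the
normal-theory form

    p = Phi((|b| - delta)/s) - Phi((-|b| - delta)/s)

with estimate ``b`` and standard error ``s``.  A standard TOST (two
one-sided tests) p-value is provided as an independent cross-check.  The
three-way verdict is read off the confidence interval: a CI wholly inside
the interval is *equivalent*, wholly outside on one side is *meaningful*,
anything else (including an endpoint touching a bound) is *inconclusive*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

from scipy import stats

from .exceptions import InvalidInputError, UnsupportedCombinationError

__all__ = ["SESOI", "EquivalenceResult", "equivalence_test", "equivalence_verdict", "tost_crosscheck"]

Rationale = Literal["theoretical", "clinical", "benchmark", "pilot", "cost_benefit"]
Verdict = Literal["equivalent", "meaningful", "inconclusive"]

#: Distance within which a CI endpoint counts as touching a SESOI bound.
BOUNDARY_TOL = 1e-12


@dataclass(frozen=True)
class SESOI:
    """A pre-declared interval of practical equivalence.

    ``rationale`` records why these bounds and not others: theory, clinical
    cutoffs, published benchmark distributions, pilot data, or cost-benefit
    reasoning.
    """

    lower: float
    upper: float
    metric: str = "beta"
    rationale: Rationale = "theoretical"
    note: str = ""

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise InvalidInputError("SESOI lower bound must be below the upper bound")

    @property
    def symmetric(self) -> bool:
        return math.isclose(self.lower, -self.upper, rel_tol=0, abs_tol=BOUNDARY_TOL)

    @classmethod
    def symmetric_about_zero(cls, delta: float, **kw) -> "SESOI":
        if delta <= 0:
            raise InvalidInputError("delta must be positive")
        return cls(lower=-delta, upper=delta, **kw)

    def to_dict(self) -> dict:
        return {
            "lower": self.lower,
            "upper": self.upper,
            "metric": self.metric,
            "rationale": self.rationale,
            "note": self.note,
        }


@dataclass(frozen=True)
class EquivalenceResult:
    estimate: float
    se: float
    sesoi: SESOI
    p_equivalence: float
    alpha: float
    ci_low: float
    ci_high: float
    ci_level: float
    verdict: Verdict

    def to_dict(self) -> dict:
        d = {
            "estimate": self.estimate,
            "se": self.se,
            "sesoi": self.sesoi.to_dict(),
            "p_equivalence": self.p_equivalence,
            "alpha": self.alpha,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_level": self.ci_level,
            "verdict": self.verdict,
        }
        return d


def equivalence_verdict(
    estimate: float,
    ci_low: float,
    ci_high: float,
    sesoi: SESOI,
) -> Verdict:
    """Three-way classification of a CI against the SESOI band.

    * ``equivalent`` — CI strictly inside (lower, upper);
    * ``meaningful`` — CI strictly outside the band on one side;
    * ``inconclusive`` — anything else, including an endpoint touching a
      bound to within ``BOUNDARY_TOL``.
    """
    if not ci_low <= estimate <= ci_high:
        raise InvalidInputError("the confidence interval must bracket the estimate")
    if ci_low > sesoi.lower + BOUNDARY_TOL and ci_high < sesoi.upper - BOUNDARY_TOL:
        return "equivalent"
    if ci_high < sesoi.lower - BOUNDARY_TOL or ci_low > sesoi.upper + BOUNDARY_TOL:
        return "meaningful"
    return "inconclusive"


def equivalence_test(
    estimate: float,
    se: float,
    sesoi: SESOI,
    alpha: float = 0.05,
) -> EquivalenceResult:
    """Normal-theory equivalence test of an estimate against a symmetric SESOI.

    The verdict uses the two-sided ``1 - 2*alpha`` confidence interval (90%
    at the default alpha = .05), the level at which CI containment and the
    TOST decision coincide.
    """
    if se <= 0:
        raise InvalidInputError("standard error must be positive")
    if not 0 < alpha < 1:
        raise InvalidInputError("alpha must lie in (0, 1)")
    if not sesoi.symmetric:
        raise UnsupportedCombinationError(
            "the normal-theory p-value is defined for a SESOI symmetric about "
            "zero; use equivalence_verdict with an explicit CI for asymmetric "
            "intervals"
        )
    delta = sesoi.upper
    b = abs(estimate)
    phi = stats.norm.cdf
    p = float(phi((b - delta) / se) - phi((-b - delta) / se))
    p = min(max(p, 0.0), 1.0)

    ci_level = 1 - 2 * alpha
    z = float(stats.norm.ppf(1 - alpha))
    ci_low = estimate - z * se
    ci_high = estimate + z * se
    verdict = equivalence_verdict(estimate, ci_low, ci_high, sesoi)
    return EquivalenceResult(
        estimate=estimate,
        se=se,
        sesoi=sesoi,
        p_equivalence=p,
        alpha=alpha,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_level=ci_level,
        verdict=verdict,
    )


def tost_crosscheck(
    estimate: float,
    se: float,
    sesoi: SESOI,
    alpha: float = 0.05,
) -> float:
    """TOST p-value: the larger of the two one-sided normal p-values
    against the SESOI bounds.

    Used as an independent oracle for the normal-theory test away from
    boundary cases; it accepts asymmetric intervals.
    """
    if se <= 0:
        raise InvalidInputError("standard error must be positive")
    phi = stats.norm.cdf
    p_upper = float(phi((estimate - sesoi.upper) / se))        # H0: b >= upper
    p_lower = float(1 - phi((estimate - sesoi.lower) / se))    # H0: b <= lower
    return max(p_upper, p_lower)
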