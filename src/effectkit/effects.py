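"""Standardized effect sizes, their conversions, and significance tests.

The statistics here are the workhorses of two-group and association analyses:
Cohen's *d* (standardized mean difference), Hedges' *g* (its small-sample
bias-corrected variant), Pearson and point-biserial correlations, the
semipartial correlation for regression terms, and odds / risk ratios for 2x2
exposure-outcome tables.  A single container, :class:`EffectEstimate`, carries
every metric together with its standard error and confidence interval, so the
equivalence-testing, benchmark, and reporting layers can treat them uniformly.

Conventions
-----------
* ``d`` uses the unweighted root-mean-square of the two group standard
  deviations, ``sqrt((s1^2 + s2^2)/2)``, as the pooled scale.  The classical
  n-weighted pooled SD is available via ``weighted_pooling=True``.
* SE for ``d`` is the large-sample normal approximation
  ``sqrt((n1+n2)/(n1*n2) + d^2 / (2*(n1+n2)))``.
* Correlation CIs use the Fisher z transform with SE ``1/sqrt(n-3)``.
* OR / RR intervals are Wald intervals on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    InvalidInputError,
    UndefinedCorrelationError,
    ZeroCellError,
)

__all__ = [
    "TwoGroupSummary",
    "EffectEstimate",
    "SignificanceResult",
    "ContingencyTable",
    "cohens_d",
    "hedges_g",
    "d_to_r",
    "r_to_d",
    "pearson_r",
    "point_biserial",
    "semipartial_r",
    "odds_ratio",
    "risk_ratio",
    "significance_tests",
    "t_test",
]

Metric = Literal["d", "g", "r", "r_pb", "r_sp", "beta", "OR", "RR", "r_squared"]

_R_FAMILY = {"r", "r_pb", "r_sp", "beta"}


@dataclass(frozen=True)
class TwoGroupSummary:
    """Summary statistics for two independent groups.

    Group 1 and group 2 are interchangeable for the magnitude of *d*; keep a
    consistent order if the sign/direction matters downstream.
    """

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def __post_init__(self) -> None:
        if not (self.sd1 > 0 and self.sd2 > 0):
            raise InvalidInputError("group standard deviations must be positive")
        if self.n1 < 2 or self.n2 < 2:
            raise InvalidInputError("each group needs at least 2 observations")

    @classmethod
    def from_samples(cls, group1: Sequence[float], group2: Sequence[float]) -> "TwoGroupSummary":
        g1 = np.asarray(group1, dtype=float)
        g2 = np.asarray(group2, dtype=float)
        if g1.size < 2 or g2.size < 2:
            raise InvalidInputError("each group needs at least 2 observations")
        return cls(
            mean1=float(g1.mean()),
            sd1=float(g1.std(ddof=1)),
            n1=int(g1.size),
            mean2=float(g2.mean()),
            sd2=float(g2.std(ddof=1)),
            n2=int(g2.size),
        )


@dataclass(frozen=True)
class EffectEstimate:
    """A point effect estimate with optional uncertainty.

    The lingua franca between modules: equivalence tests, benchmark placement
    and reports all consume this container.
    """

    metric: Metric
    value: float
    se: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_level: float = 0.95
    n_total: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise InvalidInputError("ci_level must lie in (0, 1)")
        if self.se is not None and self.se <= 0:
            raise InvalidInputError("standard error must be positive")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.value <= self.ci_high):
                raise InvalidInputError("confidence interval must bracket the value")
        if self.metric in _R_FAMILY and abs(self.value) > 1:
            raise InvalidInputError(f"{self.metric} must lie in [-1, 1]")
        if self.metric in {"OR", "RR"} and self.value <= 0:
            raise InvalidInputError(f"{self.metric} must be positive")
        if self.metric == "r_squared" and not 0 <= self.value <= 1:
            raise InvalidInputError("r_squared must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "value": self.value,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_level": self.ci_level,
            "n_total": self.n_total,
        }


@dataclass(frozen=True)
class SignificanceResult:
    """One formulation of the two-group significance test."""

    statistic: float
    df: float
    p_value: float
    formulation: Literal["mean_difference", "slope", "correlation"]


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 exposure-outcome table.

    ``a`` exposed cases, ``b`` unexposed cases, ``c`` exposed controls,
    ``d`` unexposed controls.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise InvalidInputError(f"cell '{name}' must be a non-negative integer")
        if self.a + self.b + self.c + self.d < 1:
            raise InvalidInputError("the table must contain at least one observation")


def _z(ci_level: float) -> float:
    return float(stats.norm.ppf(0.5 + ci_level / 2))


def cohens_d(
    summary: TwoGroupSummary,
    *,
    weighted_pooling: bool = False,
    ci_level: float = 0.95,
) -> EffectEstimate:
    """Standardized mean difference |mean1 - mean2| / pooled SD.

    By default the pooled SD is the unweighted root mean square
    ``sqrt((sd1^2 + sd2^2)/2)``; with ``weighted_pooling=True`` the
    df-weighted pooled SD is used instead.
    """
    s = summary
    if weighted_pooling:
        pooled = math.sqrt(
            ((s.n1 - 1) * s.sd1**2 + (s.n2 - 1) * s.sd2**2) / (s.n1 + s.n2 - 2)
        )
    else:
        pooled = math.sqrt((s.sd1**2 + s.sd2**2) / 2)
    d = abs(s.mean1 - s.mean2) / pooled
    n1, n2 = s.n1, s.n2
    se = math.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    z = _z(ci_level)
    return EffectEstimate(
        metric="d",
        value=d,
        se=se,
        ci_low=d - z * se,
        ci_high=d + z * se,
        ci_level=ci_level,
        n_total=n1 + n2,
    )


def hedges_g(d_est: EffectEstimate, n1: int, n2: int) -> EffectEstimate:
    """Small-sample bias correction of *d*: g = d * J, J = 1 - 3/(4N - 9)."""
    if d_est.metric != "d":
        raise InvalidInputError("hedges_g expects a 'd' estimate")
    n_total = n1 + n2
    if n_total <= 2:
        raise InvalidInputError("n1 + n2 must exceed 2 for the bias correction")
    j = 1 - 3 / (4 * n_total - 9)
    return EffectEstimate(
        metric="g",
        value=d_est.value * j,
        se=None if d_est.se is None else d_est.se * j,
        ci_low=None if d_est.ci_low is None else d_est.ci_low * j,
        ci_high=None if d_est.ci_high is None else d_est.ci_high * j,
        ci_level=d_est.ci_level,
        n_total=n_total,
    )


def d_to_r(d: float) -> float:
    """Convert a standardized mean difference to a correlation,
    r = d / sqrt(d^2 + 4) (equal group sizes assumed)."""
    if not math.isfinite(d):
        raise InvalidInputError("d must be finite")
    return d / math.sqrt(d**2 + 4)


def r_to_d(r: float) -> float:
    """Convert a correlation to a standardized mean difference,
    d = 2 r / sqrt(1 - r^2)."""
    if abs(r) >= 1:
        raise InvalidInputError("|r| must be < 1")
    return 2 * r / math.sqrt(1 - r**2)


def _fisher_ci(r: float, n: int, ci_level: float) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(se_z-back-transformed CI) via Fisher z; returns (se, lo, hi)."""
    if n <= 3 or abs(r) >= 1:
        return None, None, None
    z = math.atanh(r)
    se_z = 1 / math.sqrt(n - 3)
    zc = _z(ci_level)
    return se_z, math.tanh(z - zc * se_z), math.tanh(z + zc * se_z)


def pearson_r(
    x: Sequence[float],
    y: Sequence[float],
    *,
    metric: Metric = "r",
    ci_level: float = 0.95,
) -> EffectEstimate:
    """Pearson product-moment correlation with a Fisher-z confidence interval."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise InvalidInputError("x and y must be 1-d vectors of equal length")
    if xa.size < 3:
        raise InvalidInputError("at least 3 paired observations are required")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCorrelationError("correlation is undefined for constant input")
    r = float(stats.pearsonr(xa, ya).statistic)
    r = max(-1.0, min(1.0, r))
    se_z, lo, hi = _fisher_ci(r, xa.size, ci_level)
    # clamp: with |r| = 1 the transform degenerates
    if lo is not None:
        lo, hi = min(lo, r), max(hi, r)
    return EffectEstimate(
        metric=metric,
        value=r,
        se=se_z,
        ci_low=lo,
        ci_high=hi,
        ci_level=ci_level,
        n_total=int(xa.size),
    )


def point_biserial(
    values: Sequence[float],
    group: Sequence,
    *,
    ci_level: float = 0.95,
) -> EffectEstimate:
    """Correlation between a continuous variable and a binary label.

    Defined as (and computed exactly as) the Pearson correlation of the
    values with a 0/1 dummy coding of the labels.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(group)
    labels = np.unique(g)
    if labels.size != 2:
        raise InvalidInputError(
            f"exactly two distinct group labels are required, got {labels.size}"
        )
    dummy = (g == labels[1]).astype(float)
    est = pearson_r(v, dummy, metric="r_pb", ci_level=ci_level)
    return est


def semipartial_r(
    t_predictor: float,
    df_resid: float,
    r_squared_full: float,
) -> EffectEstimate:
    """Semipartial correlation of one regression term from its t statistic.

    r_sp = t * sqrt((1 - R^2_full) / df_resid); its square is the unique
    variance in the outcome explained by the predictor beyond the rest of
    the model.
    """
    if df_resid <= 0:
        raise InvalidInputError("df_resid must be positive")
    if not 0 <= r_squared_full < 1:
        raise InvalidInputError("r_squared_full must lie in [0, 1)")
    value = t_predictor * math.sqrt((1 - r_squared_full) / df_resid)
    value = max(-1.0, min(1.0, value))
    return EffectEstimate(metric="r_sp", value=value)


def _corrected_cells(table: ContingencyTable, continuity_correction: bool) -> tuple[float, float, float, float]:
    cells = {"a": table.a, "b": table.b, "c": table.c, "d": table.d}
    if continuity_correction and any(v == 0 for v in cells.values()):
        return tuple(v + 0.5 for v in cells.values())  # type: ignore[return-value]
    return float(table.a), float(table.b), float(table.c), float(table.d)


def odds_ratio(
    table: ContingencyTable,
    *,
    continuity_correction: bool = False,
    ci_level: float = 0.95,
) -> EffectEstimate:
    """Odds ratio (a*d)/(b*c) with a Wald interval on the log scale."""
    for name in ("a", "b", "c", "d"):
        if getattr(table, name) == 0 and not continuity_correction:
            raise ZeroCellError(name)
    a, b, c, d = _corrected_cells(table, continuity_correction)
    value = (a * d) / (b * c)
    se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = _z(ci_level)
    return EffectEstimate(
        metric="OR",
        value=value,
        se=se_log,
        ci_low=math.exp(math.log(value) - z * se_log),
        ci_high=math.exp(math.log(value) + z * se_log),
        ci_level=ci_level,
        n_total=int(table.a + table.b + table.c + table.d),
    )


def risk_ratio(
    table: ContingencyTable,
    *,
    continuity_correction: bool = False,
    ci_level: float = 0.95,
) -> EffectEstimate:
    """Risk ratio (a/(a+b)) / (c/(c+d)) with a Wald interval on the log scale."""
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise InvalidInputError("both exposure arms must be non-empty")
    if table.c == 0 and not continuity_correction:
        raise ZeroCellError("c")
    if table.a == 0 and not continuity_correction:
        raise ZeroCellError("a")
    a, b, c, d = _corrected_cells(table, continuity_correction)
    risk1 = a / (a + b)
    risk2 = c / (c + d)
    value = risk1 / risk2
    se_log = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    z = _z(ci_level)
    return EffectEstimate(
        metric="RR",
        value=value,
        se=se_log,
        ci_low=math.exp(math.log(value) - z * se_log),
        ci_high=math.exp(math.log(value) + z * se_log),
        ci_level=ci_level,
        n_total=int(table.a + table.b + table.c + table.d),
    )


def t_test(
    group1: Sequence[float],
    group2: Sequence[float],
    *,
    equal_var: bool = True,
) -> SignificanceResult:
    """Two-sample t test of the mean difference.

    ``equal_var=False`` gives the Welch test; only the equal-variance form
    participates in the three-formulation identity of
    :func:`significance_tests`.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise InvalidInputError("each group needs at least 2 observations")
    res = stats.ttest_ind(g1, g2, equal_var=equal_var)
    return SignificanceResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        formulation="mean_difference",
    )


def significance_tests(
    group1: Sequence[float],
    group2: Sequence[float],
) -> list[SignificanceResult]:
    """The same two-group hypothesis test in three algebraically
    equivalent guises.

    1. equal-variance t test of the mean difference,
    2. t test of the regression slope on a 0/1 group dummy (OLS),
    3. t test of the (point-biserial) correlation,
       t = r * sqrt(df / (1 - r^2)).

    All three return the identical statistic and p-value up to floating
    point error; they differ only in the standardized effect size each
    naturally reports.
    """
    import statsmodels.api as sm

    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise InvalidInputError("each group needs at least 2 observations")
    y = np.concatenate([g1, g2])
    if np.ptp(y) == 0:
        raise InvalidInputError("degenerate data: all observations identical")
    dummy = np.concatenate([np.ones(g1.size), np.zeros(g2.size)])

    results = [t_test(g1, g2, equal_var=True)]

    ols = sm.OLS(y, sm.add_constant(dummy)).fit()
    results.append(
        SignificanceResult(
            statistic=float(ols.tvalues[1]),
            df=float(ols.df_resid),
            p_value=float(ols.pvalues[1]),
            formulation="slope",
        )
    )

    r = float(np.corrcoef(dummy, y)[0, 1])
    df = y.size - 2
    if abs(r) >= 1:
        raise InvalidInputError("degenerate data: perfect separation")
    t_r = r * math.sqrt(df / (1 - r**2))
    p_r = 2 * float(stats.t.sf(abs(t_r), df))
    results.append(
        SignificanceResult(statistic=t_r, df=float(df), p_value=p_r, formulation="correlation")
    )
    return results
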