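"""Common-language translations of a standardized mean difference.

Given Cohen's *d* under the equal-variance normal model, three quantities
make the size of a group difference concrete to a non-statistical reader:

* **U3** — the proportion of the higher group lying above the lower group's
  mean, ``Phi(|d|)``;
* **overlap (OVL)** — the shared area of the two normal densities,
  ``2 * Phi(-|d|/2)``;
* **probability of superiority (PS)** — the chance that a randomly drawn
  member of the higher group exceeds a randomly drawn member of the lower
  group, ``Phi(|d| / sqrt(2))``.

A nonparametric, sample-based estimate of PS is also provided; ties are
scored as half a win, making it the sample analogue of
``P(X > Y) + 0.5 * P(X = Y)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .exceptions import InvalidInputError

__all__ = ["CommonLanguageSummary", "common_language_from_d", "prob_superiority_empirical"]


@dataclass(frozen=True)
class CommonLanguageSummary:
    u3: float
    overlap: float
    prob_superiority: float
    direction: Literal["group1_higher", "group2_higher", "none"]

    def to_dict(self) -> dict:
        return {
            "u3": self.u3,
            "overlap": self.overlap,
            "prob_superiority": self.prob_superiority,
            "direction": self.direction,
        }

    def describe(self, decimals: int = 1) -> str:
        """One-sentence plain-language rendering with percentages."""
        pct = lambda p: f"{round(p * 100, decimals):.{decimals}f}%"  # noqa: E731
        return (
            f"{pct(self.u3)} of the higher-scoring group lies above the other "
            f"group's mean (U3); the distributions overlap by {pct(self.overlap)}; "
            f"a randomly chosen member of the higher group exceeds a randomly "
            f"chosen member of the other group {pct(self.prob_superiority)} of "
            f"the time."
        )


def common_language_from_d(d: float) -> CommonLanguageSummary:
    """Translate Cohen's *d* into U3, overlap, and probability of
    superiority under the equal-variance normal model."""
    if not math.isfinite(d):
        raise InvalidInputError("d must be finite")
    ad = abs(d)
    phi = stats.norm.cdf
    if d > 0:
        direction = "group1_higher"
    elif d < 0:
        direction = "group2_higher"
    else:
        direction = "none"
    return CommonLanguageSummary(
        u3=float(phi(ad)),
        overlap=float(2 * phi(-ad / 2)),
        prob_superiority=float(phi(ad / math.sqrt(2))),
        direction=direction,
    )


def prob_superiority_empirical(
    group1: Sequence[float],
    group2: Sequence[float],
) -> float:
    """Fraction of all (group1, group2) pairs in which the group1 value is
    larger, counting ties as half.

    Equals the Mann-Whitney U statistic divided by n1*n2, so it is computed
    through the rank formulation rather than by enumerating all pairs.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    u1 = stats.mannwhitneyu(g1, g2, alternative="two-sided", method="asymptotic").statistic
    return float(u1) / (g1.size * g2.size)
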