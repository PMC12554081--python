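"""Clinical-significance tools: reliable change and normative comparison.

Two complementary questions arise when judging whether an individual or a
treated group has changed in a *clinically* meaningful way:

* Has this person changed more than measurement error alone would produce?
  The **reliable change index (RCI)** divides the pre-to-post difference by
  the standard error of the difference implied by the instrument's
  reliability:  RCI = (x2 - x1) / sqrt(2 * (s1 * sqrt(1 - rxx))^2).
* Has the treated group returned to the level of an unaffected reference
  group?  **Normative comparison** phrases this as an equivalence test of
  the post-treatment treated-vs-normative difference against a SESOI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .equivalence import SESOI, EquivalenceResult, equivalence_test
from .exceptions import InvalidInputError

__all__ = ["RCIInput", "RCIResult", "reliable_change_index", "normative_comparison"]


@dataclass(frozen=True)
class RCIInput:
    """Scores and psychometrics needed for a reliable change index.

    ``s1`` is the baseline standard deviation (from the study sample or
    reported for the instrument); ``rxx`` is the instrument's reliability
    coefficient.
    """

    x1: float
    x2: float
    s1: float
    rxx: float

    def __post_init__(self) -> None:
        if self.s1 <= 0:
            raise InvalidInputError("baseline SD must be positive")
        if not 0 <= self.rxx < 1:
            if self.rxx == 1:
                raise InvalidInputError(
                    "perfect reliability (rxx = 1) makes the RCI denominator zero"
                )
            raise InvalidInputError("reliability must lie in [0, 1)")


@dataclass(frozen=True)
class RCIResult:
    value: float
    threshold: float
    reliable_change: bool
    direction: Literal["improved", "deteriorated", "none"]

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "threshold": self.threshold,
            "reliable_change": self.reliable_change,
            "direction": self.direction,
        }


def reliable_change_index(
    input: RCIInput,
    threshold: float = 1.96,
    *,
    higher_is_worse: bool = True,
) -> RCIResult:
    """Reliable change index on the z scale with a classification.

    The default threshold 1.96 is the conventional two-sided 5% criterion.
    ``higher_is_worse`` fixes the polarity of the instrument: with the
    default, a score *decrease* counts as improvement.
    """
    if threshold <= 0:
        raise InvalidInputError("threshold must be positive")
    sem = input.s1 * math.sqrt(1 - input.rxx)
    value = (input.x2 - input.x1) / math.sqrt(2 * sem**2)
    reliable = abs(value) > threshold
    if not reliable:
        direction: Literal["improved", "deteriorated", "none"] = "none"
    else:
        went_down = value < 0
        improved = went_down if higher_is_worse else not went_down
        direction = "improved" if improved else "deteriorated"
    return RCIResult(value=value, threshold=threshold, reliable_change=reliable, direction=direction)


def normative_comparison(
    treated_estimate: float,
    treated_se: float,
    sesoi: SESOI,
    alpha: float = 0.05,
) -> EquivalenceResult:
    """Equivalence test of the post-treatment treated-vs-normative difference.

    A semantic wrapper over :func:`effectkit.equivalence.equivalence_test`:
    an ``equivalent`` verdict is read as "returned to normative levels".
    """
    return equivalence_test(treated_estimate, treated_se, sesoi, alpha)
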