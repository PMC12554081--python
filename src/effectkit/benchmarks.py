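"""Published benchmark distributions for contextualizing effect sizes.

The "compare" step: rather than labelling an effect small or large in the
abstract, place it against anchors from the literature — Cohen's
conventional guidelines, Ferguson's recommended minimums for practical
significance, the empirical percentile tables of Lovakov & Agadullina
(social psychology) and Brydges (gerontology), the ABCD-wide correlation
quartiles of Owens et al., and the Chen et al. odds-ratio anchors.

Anchor values are stored verbatim as printed in their sources and are never
recomputed; placement works on the magnitude of the effect, with the sign
reported separately by the caller.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Optional

from .effects import EffectEstimate, d_to_r, r_to_d
from .exceptions import IncompatibleMetricError, InvalidInputError

__all__ = [
    "BenchmarkTable",
    "BenchmarkPlacement",
    "list_benchmarks",
    "get_benchmark",
    "place_effect",
    "table_from_json",
    "table_to_json",
]

Relation = Literal["below_smallest", "at_anchor", "between", "above_largest"]


def _decimals(x: float) -> int:
    """Number of decimals in the shortest repr of an anchor value."""
    s = f"{x!r}"
    return len(s.split(".")[1]) if "." in s else 0


@dataclass(frozen=True)
class BenchmarkTable:
    """An ordered set of named anchor values for one effect metric."""

    name: str
    metric: str
    anchors: tuple[tuple[str, float], ...]
    source: str

    def __post_init__(self) -> None:
        values = [abs(v) for _, v in self.anchors]
        if not values:
            raise InvalidInputError("a benchmark table needs at least one anchor")
        if any(b <= a for a, b in zip(values, values[1:])):
            raise InvalidInputError("anchor magnitudes must be strictly increasing")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.anchors)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(value for _, value in self.anchors)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "metric": self.metric,
            "anchors": [{"label": l, "value": v} for l, v in self.anchors],
            "source": self.source,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkTable":
        return cls(
            name=d["name"],
            metric=d["metric"],
            anchors=tuple((a["label"], float(a["value"])) for a in d["anchors"]),
            source=d.get("source", ""),
        )


@dataclass(frozen=True)
class BenchmarkPlacement:
    table: str
    label: str
    relation: Relation
    lower_anchor: Optional[tuple[str, float]]
    upper_anchor: Optional[tuple[str, float]]
    value: float

    def to_dict(self) -> dict:
        return {
            "table": self.table,
            "label": self.label,
            "relation": self.relation,
            "lower_anchor": list(self.lower_anchor) if self.lower_anchor else None,
            "upper_anchor": list(self.upper_anchor) if self.upper_anchor else None,
            "value": self.value,
        }


_BUILTIN: dict[str, BenchmarkTable] = {
    t.name: t
    for t in [
        BenchmarkTable(
            "cohen_d", "d",
            (("small", 0.2), ("medium", 0.5), ("large", 0.8)),
            "Cohen (1988) conventional guidelines",
        ),
        BenchmarkTable(
            "cohen_r", "r",
            (("small", 0.1), ("medium", 0.3), ("large", 0.5)),
            "Cohen (1988) conventional guidelines",
        ),
        BenchmarkTable(
            "ferguson_r", "r",
            (("recommended_minimum", 0.20), ("moderate", 0.5), ("strong", 0.8)),
            "Ferguson (2009) practical-significance minimums",
        ),
        BenchmarkTable(
            "ferguson_d", "d",
            (("recommended_minimum", 0.41), ("moderate", 1.15), ("strong", 2.70)),
            "Ferguson (2009) practical-significance minimums",
        ),
        BenchmarkTable(
            "lovakov_r", "r",
            (("q25", 0.12), ("q50", 0.24), ("q75", 0.41)),
            "Lovakov & Agadullina (2021) social-psychology percentiles",
        ),
        BenchmarkTable(
            "lovakov_d", "d",
            (("q25", 0.15), ("q50", 0.36), ("q75", 0.65)),
            "Lovakov & Agadullina (2021) social-psychology percentiles",
        ),
        BenchmarkTable(
            "brydges_r", "r",
            (("q25", 0.12), ("q50", 0.20), ("q75", 0.32)),
            "Brydges (2019) gerontology percentiles",
        ),
        BenchmarkTable(
            "brydges_g", "g",
            (("q25", 0.16), ("q50", 0.38), ("q75", 0.76)),
            "Brydges (2019) gerontology percentiles",
        ),
        BenchmarkTable(
            "owens_abcd_r", "r",
            (("q25", 0.03), ("q50", 0.05), ("q75", 0.09)),
            "Owens et al. (2021) ABCD baseline correlation quartiles",
        ),
        BenchmarkTable(
            "chen_or", "OR",
            (("small", 1.68), ("medium", 3.47), ("large", 6.71)),
            "Chen, Cohen & Chen (2010) odds-ratio anchors",
        ),
    ]
}

#: Metrics treated as interchangeable for placement without conversion.
_COMPATIBLE = {
    "d": {"d", "g"},
    "g": {"d", "g"},
    "r": {"r", "r_pb", "r_sp", "beta"},
    "OR": {"OR"},
    "RR": {"RR"},
}


def list_benchmarks() -> list[BenchmarkTable]:
    """All built-in benchmark tables, anchors exactly as printed in their
    sources."""
    return list(_BUILTIN.values())


def get_benchmark(name: str) -> BenchmarkTable:
    try:
        return _BUILTIN[name]
    except KeyError:
        raise InvalidInputError(
            f"unknown benchmark table '{name}'; available: {sorted(_BUILTIN)}"
        ) from None


def place_effect(
    effect: EffectEstimate,
    table: "BenchmarkTable | str",
    *,
    convert: Optional[Literal["d_to_r", "r_to_d"]] = None,
) -> BenchmarkPlacement:
    """Locate |effect| against a table's anchor sequence.

    Metrics must match the table (d/g and the r family are each treated as
    one group); a cross-family comparison requires an explicit ``convert``
    — it is never applied silently.  An effect equal to an anchor at the
    anchor's printed precision is reported as sitting *at* that anchor;
    otherwise the bracketing anchors are returned.
    """
    if isinstance(table, str):
        table = get_benchmark(table)
    value = effect.value
    metric = effect.metric
    if convert == "d_to_r":
        if metric not in _COMPATIBLE["d"]:
            raise IncompatibleMetricError("d_to_r conversion requires a d-family effect")
        value = d_to_r(value)
        metric = "r"
    elif convert == "r_to_d":
        if metric not in _COMPATIBLE["r"]:
            raise IncompatibleMetricError("r_to_d conversion requires an r-family effect")
        value = r_to_d(value)
        metric = "d"
    elif convert is not None:
        raise InvalidInputError(f"unknown conversion '{convert}'")

    compatible = _COMPATIBLE.get(table.metric, {table.metric})
    if metric not in compatible:
        raise IncompatibleMetricError(
            f"effect metric '{metric}' is incompatible with table metric "
            f"'{table.metric}'; pass convert='d_to_r' or 'r_to_d' explicitly"
        )

    mag = abs(value)
    labels, values = table.labels, [abs(v) for v in table.values]

    for label, anchor in zip(labels, values):
        if round(mag, _decimals(anchor)) == anchor:
            return BenchmarkPlacement(table.name, label, "at_anchor",
                                      (label, anchor), (label, anchor), value)
    if mag < values[0]:
        return BenchmarkPlacement(table.name, labels[0], "below_smallest",
                                  None, (labels[0], values[0]), value)
    if mag > values[-1]:
        return BenchmarkPlacement(table.name, labels[-1], "above_largest",
                                  (labels[-1], values[-1]), None, value)
    for i in range(len(values) - 1):
        if values[i] < mag < values[i + 1]:
            nearest = labels[i] if mag - values[i] <= values[i + 1] - mag else labels[i + 1]
            return BenchmarkPlacement(table.name, nearest, "between",
                                      (labels[i], values[i]),
                                      (labels[i + 1], values[i + 1]), value)
    # unreachable for strictly increasing anchors
    raise InvalidInputError("could not place effect against the anchor sequence")


def table_to_json(table: BenchmarkTable) -> str:
    return json.dumps(table.to_dict(), indent=2)


def table_from_json(text: str) -> BenchmarkTable:
    """Load a user-defined table from the JSON schema
    ``{name, metric, anchors: [{label, value}], source}``."""
    return BenchmarkTable.from_dict(json.loads(text))
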