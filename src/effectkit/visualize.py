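"""Estimation graphics: overlap, equivalence (forest), and bootstrap plots.

Three idioms recur when communicating effect sizes:

* **overlap plots** — simulated point clouds for two groups at a given
  standardized difference, annotated with the common-language summary;
* **equivalence plots** — a forest-style layout of estimates and CIs
  against the shaded SESOI band, color-coded by verdict;
* **estimation plots** — raw data as a jittered swarm on the left and the
  bootstrap distribution of the mean difference with its percentile CI on
  the right, with an optional zoomed axis when the difference is tiny
  relative to the raw scale.

Every figure writes a JSON *sidecar* (same path + ``.json``) holding every
number drawn, so figures are testable without image comparison and carry
their own provenance (seed, reps).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .common_language import common_language_from_d
from .equivalence import EquivalenceResult
from .exceptions import InvalidInputError

__all__ = [
    "BootstrapDistribution",
    "bootstrap_mean_difference",
    "overlap_plot",
    "equivalence_plot",
    "estimation_plot",
]

#: Zoomed delta axis activates when CI width / raw range falls below this.
ZOOM_THRESHOLD = 0.02

_VERDICT_COLORS = {"equivalent": "#2c7fb8", "meaningful": "#d95f02", "inconclusive": "#7570b3"}


@dataclass(frozen=True)
class BootstrapDistribution:
    """Bootstrap draws of a statistic with a percentile CI.

    ``ci_low``/``ci_high`` are exactly the (1-level)/2 and 1-(1-level)/2
    quantiles of ``draws``.
    """

    statistic: Literal["mean_difference"]
    draws: np.ndarray
    point_estimate: float
    ci_low: float
    ci_high: float
    ci_level: float
    reps: int
    seed: int

    def to_dict(self, include_draws: bool = True) -> dict:
        d = {
            "statistic": self.statistic,
            "point_estimate": self.point_estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_level": self.ci_level,
            "reps": self.reps,
            "seed": self.seed,
        }
        if include_draws:
            d["draws"] = [float(x) for x in self.draws]
        return d


def bootstrap_mean_difference(
    group1: Sequence[float],
    group2: Sequence[float],
    reps: int = 5000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> BootstrapDistribution:
    """Nonparametric bootstrap of mean(group1) - mean(group2).

    Resamples within each group with replacement; the CI is the percentile
    interval of the draws.  Deterministic for a fixed seed.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise InvalidInputError("each group needs at least 2 observations")
    if reps < 100:
        raise InvalidInputError("reps must be at least 100")
    if not 0 < ci_level < 1:
        raise InvalidInputError("ci_level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    draws = np.empty(reps)
    chunk = max(1, min(reps, int(2e7 // max(g1.size, g2.size))))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        idx1 = rng.integers(0, g1.size, size=(m, g1.size))
        idx2 = rng.integers(0, g2.size, size=(m, g2.size))
        draws[done:done + m] = g1[idx1].mean(axis=1) - g2[idx2].mean(axis=1)
        done += m
    # round the tail probability so e.g. ci_level=0.9 queries exactly 0.05
    q_lo = round((1 - ci_level) / 2, 12)
    lo, hi = np.quantile(draws, [q_lo, 1 - q_lo])
    return BootstrapDistribution(
        statistic="mean_difference",
        draws=draws,
        point_estimate=float(g1.mean() - g2.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=ci_level,
        reps=reps,
        seed=seed,
    )


def _write_sidecar(output: Path, payload: dict) -> Path:
    sidecar = output.with_name(output.name + ".json")
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return sidecar


def _jitter(rng: np.random.Generator, n: int, width: float = 0.18) -> np.ndarray:
    return rng.uniform(-width, width, n)


def overlap_plot(
    d: float,
    n_points_per_group: int = 200,
    seed: int = 0,
    output: "str | Path" = "overlap.svg",
) -> Path:
    """Two simulated point clouds at separation *d*, annotated with the
    common-language summary (U3, overlap, probability of superiority)."""
    if n_points_per_group < 1:
        raise InvalidInputError("n_points_per_group must be at least 1")
    output = Path(output)
    rng = np.random.default_rng(seed)
    g1 = rng.normal(d, 1.0, n_points_per_group)
    g2 = rng.normal(0.0, 1.0, n_points_per_group)
    cl = common_language_from_d(d)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(_jitter(rng, g1.size) + 1, g1, s=12, alpha=0.6, label="group 1")
    ax.scatter(_jitter(rng, g2.size) + 2, g2, s=12, alpha=0.6, label="group 2")
    ax.hlines([g1.mean(), g2.mean()], [0.75, 1.75], [1.25, 2.25], colors="k", lw=1.5)
    ax.set_xticks([1, 2], ["group 1", "group 2"])
    ax.set_ylabel("value (SD units)")
    ax.set_title(f"d = {d:g}")
    note = (
        f"U3 = {cl.u3 * 100:.1f}%\n"
        f"overlap = {cl.overlap * 100:.1f}%\n"
        f"P(superiority) = {cl.prob_superiority * 100:.1f}%"
    )
    ax.annotate(note, xy=(0.02, 0.98), xycoords="axes fraction", va="top", fontsize=9)
    fig.tight_layout()
    fig.savefig(output)
    plt.close(fig)

    _write_sidecar(output, {
        "kind": "overlap",
        "d": d,
        "seed": seed,
        "n_points_per_group": n_points_per_group,
        "common_language": cl.to_dict(),
        "group1": [float(x) for x in g1],
        "group2": [float(x) for x in g2],
    })
    return output


def equivalence_plot(
    results: Sequence[EquivalenceResult],
    output: "str | Path" = "equivalence.svg",
    labels: Optional[Sequence[str]] = None,
) -> Path:
    """Forest-style plot of estimates and CIs against the SESOI band.

    Rows render in the order given (no sorting); the band edges sit exactly
    at the SESOI bounds and points are color-coded by verdict.
    """
    if len(results) == 0:
        raise InvalidInputError("at least one equivalence result is required")
    output = Path(output)
    if labels is None:
        labels = [f"effect {i + 1}" for i in range(len(results))]
    sesoi = results[0].sesoi

    fig, ax = plt.subplots(figsize=(6, 1 + 0.5 * len(results)))
    ax.axvspan(sesoi.lower, sesoi.upper, color="0.88", zorder=0, label="SESOI")
    ax.axvline(0, color="0.4", lw=0.8)
    ys = np.arange(len(results))[::-1]
    for y, res, label in zip(ys, results, labels):
        c = _VERDICT_COLORS[res.verdict]
        ax.plot([res.ci_low, res.ci_high], [y, y], color=c, lw=2)
        ax.plot(res.estimate, y, "o", color=c, ms=6)
    ax.set_yticks(ys, labels)
    ax.set_xlabel(f"{sesoi.metric} with {results[0].ci_level * 100:.0f}% CI")
    fig.tight_layout()
    fig.savefig(output)
    plt.close(fig)

    _write_sidecar(output, {
        "kind": "equivalence",
        "sesoi": sesoi.to_dict(),
        "rows": [
            {"label": label, **res.to_dict()}
            for label, res in zip(labels, results)
        ],
    })
    return output


def estimation_plot(
    group1: Sequence[float],
    group2: Sequence[float],
    reps: int = 5000,
    seed: int = 0,
    output: "str | Path" = "estimation.svg",
    ci_level: float = 0.95,
    zoom_threshold: float = ZOOM_THRESHOLD,
) -> Path:
    """Two-panel estimation plot: raw swarm left, bootstrap delta right.

    When the bootstrap CI width is below ``zoom_threshold`` times the raw
    data range, the delta panel zooms to the CI neighborhood (the
    "magnifying glass" idiom for tiny effects in huge samples).
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    boot = bootstrap_mean_difference(g1, g2, reps=reps, ci_level=ci_level, seed=seed)
    output = Path(output)

    raw_range = float(np.ptp(np.concatenate([g1, g2])))
    ci_width = boot.ci_high - boot.ci_low
    zoomed = raw_range > 0 and ci_width < zoom_threshold * raw_range

    rng = np.random.default_rng(seed + 1)
    fig, (ax_raw, ax_delta) = plt.subplots(
        1, 2, figsize=(8, 4), gridspec_kw={"width_ratios": [2, 1]}
    )
    ax_raw.scatter(_jitter(rng, g1.size) + 1, g1, s=8, alpha=0.5)
    ax_raw.scatter(_jitter(rng, g2.size) + 2, g2, s=8, alpha=0.5)
    ax_raw.hlines([g1.mean(), g2.mean()], [0.75, 1.75], [1.25, 2.25], colors="k", lw=1.5)
    ax_raw.set_xticks([1, 2], ["group 1", "group 2"])
    ax_raw.set_ylabel("raw value")

    ax_delta.hist(boot.draws, bins=60, orientation="horizontal", color="#fc8d62")
    ax_delta.axhline(boot.point_estimate, color="k", lw=1.2)
    ax_delta.axhline(boot.ci_low, color="k", lw=0.8, ls="--")
    ax_delta.axhline(boot.ci_high, color="k", lw=0.8, ls="--")
    ax_delta.axhline(0, color="0.4", lw=0.8)
    ax_delta.set_ylabel(r"mean difference $\Delta$")
    if zoomed:
        pad = 2 * ci_width
        ax_delta.set_ylim(boot.ci_low - pad, boot.ci_high + pad)
        ax_delta.set_title("zoomed", fontsize=9)
    fig.tight_layout()
    fig.savefig(output)
    plt.close(fig)

    _write_sidecar(output, {
        "kind": "estimation",
        "seed": seed,
        "reps": reps,
        "n_group1": int(g1.size),
        "n_group2": int(g2.size),
        "zoomed": bool(zoomed),
        "raw_range": raw_range,
        "bootstrap": boot.to_dict(include_draws=True),
    })
    return output
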