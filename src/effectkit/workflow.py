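"""The define-compare-test-visualize workflow.

One call runs the full interpretive pipeline on a two-group dataset:

1. **define** — the pre-declared SESOI (refusing to run without one);
2. **compare** — effect estimates placed against benchmark tables;
3. **test** — the equivalence test of the estimate against the SESOI;
4. **visualize** — overlap, estimation, and equivalence figures.

The report is written both as deterministic JSON (every number in the
human-readable rendering is also here) and as Markdown.  Provenance — the
seed, the package version, and a hash of the canonical configuration — is
embedded in every report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .benchmarks import place_effect
from .common_language import common_language_from_d, prob_superiority_empirical
from .effects import TwoGroupSummary, cohens_d, d_to_r, hedges_g, point_biserial
from .equivalence import SESOI, equivalence_test
from .exceptions import ConfigError, DataError, EffectKitError, NumericError
from .io import read_table, split_two_groups, write_json
from .visualize import equivalence_plot, estimation_plot, overlap_plot

__all__ = ["AnalysisConfig", "Report", "run_workflow"]

_MISSING_SESOI_MSG = (
    "no SESOI declared: define the smallest effect size of interest upfront "
    "(bounds plus a rationale) before testing; the workflow will not run the "
    "test step against an interval chosen after seeing the data"
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration for one workflow run (JSON-friendly)."""

    data_path: str
    layout: str = "long"
    sesoi: Optional[SESOI] = None
    alpha: float = 0.05
    benchmarks: tuple[str, ...] = ("cohen_d", "lovakov_d")
    bootstrap_reps: int = 5000
    seed: int = 0
    output_dir: str = "effectkit_report"

    @classmethod
    def from_json(cls, path: "str | Path") -> "AnalysisConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            raw = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON ({exc})") from exc
        sesoi = None
        if "sesoi" in raw and raw["sesoi"] is not None:
            s = raw["sesoi"]
            try:
                sesoi = SESOI(
                    lower=float(s["lower"]),
                    upper=float(s["upper"]),
                    metric=s.get("metric", "d"),
                    rationale=s.get("rationale", "theoretical"),
                    note=s.get("note", ""),
                )
            except (KeyError, ValueError, EffectKitError) as exc:
                raise ConfigError(f"{path}: invalid sesoi block ({exc})") from exc
        try:
            return cls(
                data_path=raw["data_path"],
                layout=raw.get("layout", "long"),
                sesoi=sesoi,
                alpha=float(raw.get("alpha", 0.05)),
                benchmarks=tuple(raw.get("benchmarks", ("cohen_d", "lovakov_d"))),
                bootstrap_reps=int(raw.get("bootstrap_reps", 5000)),
                seed=int(raw.get("seed", 0)),
                output_dir=raw.get("output_dir", "effectkit_report"),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: invalid config ({exc})") from exc

    def canonical(self) -> dict:
        return {
            "data_path": self.data_path,
            "layout": self.layout,
            "sesoi": self.sesoi.to_dict() if self.sesoi else None,
            "alpha": self.alpha,
            "benchmarks": list(self.benchmarks),
            "bootstrap_reps": self.bootstrap_reps,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    def hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class Report:
    define: dict
    compare: dict
    test: dict
    visualize: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "define": self.define,
            "compare": self.compare,
            "test": self.test,
            "visualize": self.visualize,
            "provenance": self.provenance,
        }

    def to_markdown(self) -> str:
        d = self.to_dict()
        eff = self.compare["effects"]
        lines = [
            "# Effect-size report",
            "",
            "## 1. Define",
            f"SESOI: [{self.define['sesoi']['lower']}, {self.define['sesoi']['upper']}] "
            f"on the {self.define['sesoi']['metric']} scale "
            f"(rationale: {self.define['sesoi']['rationale']}).",
            "",
            "## 2. Compare",
            f"Cohen's d = {eff['d']['value']:.4f} "
            f"[{eff['d']['ci_low']:.4f}, {eff['d']['ci_high']:.4f}], "
            f"Hedges' g = {eff['g']['value']:.4f}, r = {eff['r']['value']:.4f}.",
            self.compare["common_language"]["description"],
            "",
        ]
        for p in self.compare["placements"]:
            lines.append(
                f"- vs `{p['table']}`: {p['relation']} (nearest anchor: {p['label']})"
            )
        t = self.test
        lines += [
            "",
            "## 3. Test",
            f"Equivalence p = {t['p_equivalence']:.6g} at alpha = {t['alpha']}; "
            f"{t['ci_level'] * 100:.0f}% CI [{t['ci_low']:.4f}, {t['ci_high']:.4f}] "
            f"-> verdict: **{t['verdict']}**.",
            "",
            "## 4. Visualize",
        ]
        for name, path in self.visualize["figures"].items():
            lines.append(f"- {name}: `{path}`")
        prov = self.provenance
        lines += [
            "",
            "---",
            f"effectkit {prov['version']} | seed {prov['seed']} | config {prov['config_hash']}",
        ]
        return "\n".join(lines) + "\n"


def run_workflow(config: AnalysisConfig) -> Report:
    """Execute define -> compare -> test -> visualize and write the report.

    Raises :class:`ConfigError` (exit 2 in the CLI) when no SESOI is
    declared, :class:`DataError` (3) on malformed input, and
    :class:`NumericError` (4) if a computation fails.
    """
    if config.sesoi is None:
        raise ConfigError(_MISSING_SESOI_MSG)
    if config.layout != "long":
        raise ConfigError("the workflow consumes a long-layout two-group CSV")

    df = read_table(config.data_path, "long")
    g1, g2, group_names = split_two_groups(df)
    if g1.size < 2 or g2.size < 2:
        raise DataError("each group needs at least 2 observations")

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        # -- compare: estimates, common language, benchmark placement
        summary = TwoGroupSummary.from_samples(g1, g2)
        d_est = cohens_d(summary)
        g_est = hedges_g(d_est, summary.n1, summary.n2)
        r_pb = point_biserial(
            df["value"].to_numpy(dtype=float),
            df["group"].to_numpy(),
        )
        pooled = ((summary.sd1**2 + summary.sd2**2) / 2) ** 0.5
        signed_d = (summary.mean1 - summary.mean2) / pooled
        cl = common_language_from_d(signed_d)
        ps_emp = prob_superiority_empirical(g1, g2)
        placements = [place_effect(d_est, name) for name in config.benchmarks]

        # -- test: equivalence of the signed estimate against the SESOI
        if config.sesoi.metric in ("d", "g"):
            estimate, se = signed_d, d_est.se
        elif config.sesoi.metric in ("r", "r_pb", "beta"):
            estimate, se = r_pb.value, r_pb.se
        else:
            raise ConfigError(
                f"workflow SESOI metric must be d/g or an r-family metric, "
                f"got '{config.sesoi.metric}'"
            )
        eq = equivalence_test(estimate, se, config.sesoi, alpha=config.alpha)

        # -- visualize
        figures = {
            "overlap": str(overlap_plot(
                signed_d, n_points_per_group=min(200, g1.size + g2.size),
                seed=config.seed, output=outdir / "overlap.svg",
            )),
            "estimation": str(estimation_plot(
                g1, g2, reps=config.bootstrap_reps, seed=config.seed,
                output=outdir / "estimation.svg",
            )),
            "equivalence": str(equivalence_plot(
                [eq], output=outdir / "equivalence.svg",
                labels=[f"{group_names[0]} vs {group_names[1]}"],
            )),
        }
    except EffectKitError:
        raise
    except (FloatingPointError, ZeroDivisionError, OverflowError) as exc:
        raise NumericError(f"computation failed: {exc}") from exc

    report = Report(
        define={"sesoi": config.sesoi.to_dict(), "alpha": config.alpha},
        compare={
            "groups": {"group1": group_names[0], "group2": group_names[1],
                       "n1": summary.n1, "n2": summary.n2},
            "effects": {
                "d": d_est.to_dict(),
                "g": g_est.to_dict(),
                "r": r_pb.to_dict(),
                "r_from_d": d_to_r(signed_d),
            },
            "common_language": {**cl.to_dict(),
                                "prob_superiority_empirical": ps_emp,
                                "description": cl.describe()},
            "placements": [p.to_dict() for p in placements],
        },
        test=eq.to_dict(),
        visualize={"figures": figures},
        provenance={
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.hash(),
            "config": config.canonical(),
        },
    )
    write_json(report.to_dict(), outdir / "report.json")
    (outdir / "report.md").write_text(report.to_markdown())
    return report
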