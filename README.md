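# effectkit

Interpret effect sizes — don't just report p-values.

In large cohort studies (tens of thousands of participants), essentially
every association is statistically significant, including ones far too
small to matter; in small studies, significant results systematically
overstate the truth. `effectkit` is a toolkit for researchers who need to
say what an effect *means*, built around a four-step workflow:

1. **Define** a smallest effect size of interest (SESOI) — an interval,
   e.g. a standardized slope of ±0.10, declared before analysis with an
   explicit rationale.
2. **Compare** the observed effect to published benchmark distributions
   (Cohen's guidelines, field-specific percentile tables, odds-ratio
   anchors).
3. **Test** it with an equivalence test, whose null hypothesis is that the
   effect lies *outside* the SESOI — rejection is statistical evidence of
   negligibility. Verdicts are three-way: equivalent / meaningful /
   inconclusive, read off the 1−2α confidence interval against the band.
4. **Visualize** with estimation graphics: overlap plots, forest-style
   equivalence plots, and two-panel bootstrap estimation plots.

## What's inside

| area | contents |
| --- | --- |
| `effectkit.effects` | Cohen's d = \|x̄₁−x̄₂\|/√((s₁²+s₂²)/2), Hedges' g, Pearson / point-biserial / semipartial r, d↔r conversions (r = d/√(d²+4), d = 2r/√(1−r²)), OR/RR with log-scale Wald CIs, and the three equivalent formulations of the two-group test (means, slope, correlation) |
| `effectkit.common_language` | U3 = Φ(\|d\|), overlap = 2Φ(−\|d\|/2), probability of superiority = Φ(\|d\|/√2), plus a tie-aware empirical variant |
| `effectkit.equivalence` | SESOI declaration; p = Φ((\|b\|−δ)/s) − Φ((−\|b\|−δ)/s); TOST cross-check; verdict logic |
| `effectkit.clinical` | reliable change index RCI = (x₂−x₁)/√(2(s₁√(1−r_xx))²), normative comparison |
| `effectkit.benchmarks` | built-in anchor tables (Cohen, Ferguson, Lovakov, Brydges, ABCD-wide quartiles, Chen OR), magnitude placement, custom JSON tables |
| `effectkit.power` | exact noncentral-t power, Fisher-z power for r, required-n search, seeded CI-width / p-instability simulations |
| `effectkit.visualize` | percentile bootstrap of the mean difference; overlap, equivalence and estimation figures, each with a JSON sidecar of every number drawn |
| `effectkit.datasets` | seeded generators: two-group normal at a given d, regression data at a given standardized slope, a heights-like fixture (population d = 1.03) |
| `effectkit.workflow` / CLI | the four-step pipeline with a deterministic JSON + Markdown report |

## Worked example

A two-group sample of 30 male and 30 female heights drawn from the
package's heights fixture:

```python
import effectkit as ek

df = ek.heights_fixture(30, seed=7)
male = df[df.group == "male"].value.to_numpy()
female = df[df.group == "female"].value.to_numpy()

summary = ek.TwoGroupSummary.from_samples(male, female)
d = ek.cohens_d(summary)
print(d.value, d.ci_low, d.ci_high)   # 0.711  0.190  1.233
print(ek.d_to_r(d.value))             # 0.335

for t in ek.significance_tests(male, female):
    print(t.formulation, round(t.statistic, 3), round(t.p_value, 4))
# mean_difference 2.755 0.0078
# slope           2.755 0.0078
# correlation     2.755 0.0078

print(ek.common_language_from_d(d.value).describe())
# 76.2% of the higher-scoring group lies above the other group's mean (U3);
# the distributions overlap by 72.2%; a randomly chosen member of the higher
# group exceeds a randomly chosen member of the other group 69.3% of the time.

print(ek.place_effect(d, "cohen_d").relation)   # between  (medium..large)
```

Reading it: the sample difference (d = 0.71, a "large-ish" effect by
Cohen's guidelines) underestimates the generator's population value
d = 1.03, and its 95% CI spans half the benchmark scale — exactly the
small-sample imprecision the power tools quantify:

```python
print(ek.power_t(ek.PowerQuery(metric="d", effect=0.5, n=30)))  # 0.478
print(ek.required_n("d", 0.5, 0.80))                            # 64 per group
```

An equivalence test of a tiny slope estimated with cohort-scale precision
(b = −0.06, SE = 0.011, SESOI ±0.10):

```python
sesoi = ek.SESOI.symmetric_about_zero(0.10, metric="beta", rationale="benchmark")
res = ek.equivalence_test(-0.06, 0.011, sesoi)
print(res.p_equivalence, res.verdict)   # 0.000138  equivalent
```

The 90% CI [−0.078, −0.042] lies wholly inside ±0.10: the effect is
reliably nonzero *and* statistically negligible at the declared SESOI —
the two statements are not in tension.

The same analyses run from the shell (`effectkit effect`, `convert`,
`cl`, `equivalence`, `rci`, `benchmark`, `power`, `required-n`,
`simulate`, `generate`, `plot`, `workflow`); `effectkit workflow
--config cfg.json` executes all four steps and writes a deterministic
JSON + Markdown report with figures and sidecars.

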