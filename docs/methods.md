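# Methods

`effectkit` implements an interpretive workflow for effect sizes in
large-sample research — **define** a smallest effect size of interest
(SESOI), **compare** observed effects to published benchmarks, **test**
them with equivalence tests, and **visualize** them with estimation
graphics. This note records the statistical definitions, the numerical
choices, what the synthetic generators do and do not emulate, and the known
limitations.

## Effect sizes and their uncertainty

**Standardized mean difference.** Cohen's *d* is
|x̄₁ − x̄₂| / √((s₁² + s₂²)/2). The pooled scale is deliberately the
*unweighted* root mean square of the two group SDs; the classical
df-weighted pooled SD is available (`weighted_pooling=True`) and coincides
with it at equal group sizes. *d* has no closed-form exact CI, so the
standard large-sample normal approximation is used:
SE(d) = √((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))). Hedges' *g* applies the
small-sample bias factor J = 1 − 3/(4N − 9) to the estimate, SE and CI
alike; J → 1 as N → ∞, so *g* → *d*.

**Correlations.** Pearson and point-biserial *r* carry a Fisher-z interval
(SE 1/√(n−3), back-transformed). The point-biserial is *defined* as the
Pearson correlation with a 0/1 dummy coding and is computed exactly that
way, so the two agree bit-for-bit. The semipartial correlation of a
regression term is recovered from its t statistic,
r_sp = t·√((1 − R²_full)/df_resid) — the identity that works for any
linear model whose t, residual df and R² are known, without refitting.
The d↔r conversions r = d/√(d²+4) and d = 2r/√(1−r²) assume equal group
sizes; no base-rate adjustment is applied.

**2×2 tables.** OR = ad/bc and RR = (a/(a+b))/(c/(c+d)) with Wald
intervals on the log scale. A zero cell is a hard error naming the cell;
an optional continuity correction adds 0.5 to every cell.

**One test, three formulations.** For two groups, the equal-variance t
test of means, the OLS t test of the slope on a group dummy, and the t
test of the point-biserial correlation (t = r√(df/(1−r²))) are the same
test; the suite checks the three statistics and p-values agree to 1e−10
over hundreds of random datasets. The three routes are computed by
genuinely different code paths (scipy's t test, a statsmodels OLS fit, the
closed form). Welch's correction is available for heteroscedastic data but
is excluded from the identity, which holds only under the equal-variance
formulation.

## Common-language translation

Under the equal-variance normal model: U3 = Φ(|d|), overlap = 2Φ(−|d|/2),
probability of superiority = Φ(|d|/√2). Sign only affects the reported
direction. The empirical probability of superiority is the Mann-Whitney U
statistic divided by n₁n₂, which scores ties as half a win — the sample
analogue of P(X>Y) + ½P(X=Y); a brute-force pairwise enumeration backs it
in the tests.

## Equivalence testing and the SESOI

A SESOI is an interval, typically ±δ about zero, declared *before*
analysis, with a recorded rationale (theoretical, clinical, benchmark,
pilot, cost-benefit). The normal-theory p-value for a symmetric interval
is p = Φ((|b| − δ)/s) − Φ((−|b| − δ)/s); p ≤ α rejects the null that the
effect lies outside the interval. Choices:

* Φ is the standard normal CDF; no t small-sample variant is offered —
  the intended use case is large-n estimates exported from fitted models.
* The formula is implemented literally, so b = 0 gives p = 0 exactly.
* The verdict is read off the two-sided 1 − 2α CI (90% at α = .05, the
  level at which CI containment and the TOST decision coincide):
  *equivalent* if the CI is strictly inside the band, *meaningful* if
  strictly outside on one side, otherwise *inconclusive* — including a CI
  endpoint touching a bound to within 1e−12.
* Asymmetric intervals are accepted by the verdict rule but rejected by
  the symmetric-form p-value rather than silently recentred.
* A TOST cross-check (max of the two one-sided normal p-values) is
  provided. It upper-bounds the normal-theory p everywhere — the two
  differ by the far-tail term Φ(−(|b|+δ)/s) — so their α-decisions are
  provably identical whenever the estimate sits ≥3 SEs clear of a bound,
  and can differ only in that margin when the SE is large relative to δ.

Normative comparison ("has the treated group returned to the level of an
unaffected reference group?") is the same machinery with the treated-vs-
normative difference as the estimate.

## Reliable change

RCI = (x₂ − x₁)/√(2·(s₁√(1−r_xx))²). The default decision threshold is
1.96, the conventional two-sided 5% criterion — the framework itself fixes
no threshold, so it is a parameter. Polarity is explicit: by default
higher scores are read as worse (symptom scales), with a flag to invert.
The baseline SD may come from the study sample or from published
psychometrics; both are just `s1`. Designs with more than two timepoints
are out of scope.

## Benchmarks

Built-in tables store anchors verbatim from their sources: Cohen's
d 0.2/0.5/0.8 and r 0.1/0.3/0.5; Ferguson's practical-significance
minimums (r 0.20/0.5/0.8, d 0.41/1.15/2.70 — stored as printed, the 2.70
is not forced through the conversion formula, which gives 2.67); the
social-psychology (Lovakov) and gerontology (Brydges) percentiles; the
ABCD-wide correlation quartiles (Owens, 0.03/0.05/0.09); and the Chen OR
anchors 1.68/3.47/6.71 (kept as constants — the base-rate assumptions
behind them are not reproducible here). Placement is by magnitude; an
effect equal to an anchor at the anchor's printed precision is "at" it,
otherwise the bracketing anchors are reported — no percentile
interpolation is invented. Cross-family comparisons (d vs an r table)
require an explicit conversion flag. Custom tables load from a small JSON
schema so meta-analysis-specific comparisons can be expressed without
shipping any external data.

## Power and precision

Power for the two-sample t test is exact noncentral-t (noncentrality
d·√(n/2), df 2n−2). Power for r uses the Fisher-z approximation
Φ(|atanh r|·√(n−3) − z_crit) plus the opposite tail; the suite bounds its
error against the normal regime and it is indistinguishable from exact at
cohort n. `required_n` bisects the monotone power function and returns the
smallest n meeting the target (minimality is asserted, not assumed).

The precision simulation draws, per replicate, two normal samples with
unit SD separated by the true effect, and records the sample d, the width
of its normal-approximation CI (the same SE formula as the estimator, for
internal consistency), and the equal-variance t-test p-value. Defaults:
1000 replicates; the cohort-scale sample size 11,865 is interpreted as
*per-group*. Sampling is chunked so memory stays flat at large n. One
seeded pass feeds both the CI-width summary and the p-value summary.

On p-value instability: the interquartile range of −log10(p) is reported
as a log-scale spread diagnostic, but note that it *grows* with power
(d(−log10 p)/dt ≈ t/ln 10 increases with the noncentrality), so it is not
by itself a stability measure. The claim that p-values are consistent only
in well-powered designs shows up on the probability scale: at power ≈ 0.5
the IQR of p spans the decision threshold, while at power > 0.99 it
collapses by orders of magnitude. The tests assert the p-scale version.

## Bootstrap and figures

The estimation graphic uses a nonparametric percentile bootstrap of the
mean difference (resampling within each group), default 5000 replicates,
seeded. BCa is not implemented. The CI endpoints are exactly the
configured quantiles of the draws (the tail probability is rounded at the
12th decimal so a 90% level queries exactly 0.05/0.95). Every figure
writes a JSON sidecar containing all numbers drawn — points, draws, CIs,
seed, reps — so rendering is testable and reproducible without pixel
comparison. The delta panel zooms to the CI neighborhood when the CI width
is below 2% of the raw data range; that threshold is a heuristic of this
package, configurable per call.

## Synthetic data

Generators are pure functions of (parameters, seed) using NumPy's default
PCG64 generator. `two_group_normal` and `regression_slope_data` are
unit-variance so d and β are the population parameters directly;
covariates in the regression generator are independent noise predictors
with zero coefficients. The heights fixture draws from N(175.3, 13.5922²)
and N(161.3, 13.5922²) cm — the common SD is back-solved to four decimals
so the population standardized difference is 1.03.

What the generators do *not* emulate: heteroscedasticity between groups,
non-normal tails, measurement error, correlated covariates, or nested
(site/family) designs. Passing tests therefore demonstrate correctness of
the statistics under their stated model, not robustness to those
violations; the Welch option and the nonparametric probability of
superiority are the only concessions to model failure.

## Problem sizes in the test suite

The suite favours sizes that make Monte-Carlo error negligible relative to
each tolerance: 1000 replicates for the precision simulation (matching the
documented default), 50,000 per group for the probability-of-superiority
convergence bound (±0.01), 10,000–60,000 for parameter-recovery checks,
500 random datasets for the three-formulation identity, and 10,000 grid
points for the TOST comparison. The full suite runs in well under a
minute on a single CPU.

## Known limitations

* No mixed-model fitting: multilevel estimates enter as (estimate, SE)
  pairs from upstream software.
* d↔r conversions assume equal group sizes; no base-rate-adjusted forms.
* No equivalence tests on the Fisher-z scale for correlations.
* The d CI is a normal approximation, slightly narrow at very small n.
* The OR/RR layer offers no McNemar test for paired tables and no
  base-rate-aware common-language translation beyond the "x% more likely"
  phrasing.
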