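# Methods

## Scoring model

Each well of a 384-well organoid viability screen is normalized to the
mean of its model's day-0 seeding-control wells within the same biological
replicate (falling back to the pooled day-0 mean, with a warning, if a
replicate has no day-0 plate). From the fold-changes `T/T0` (treated) and
`C/T0` (vehicle) the package computes three response scales per well:

- GR value: `2^(log2(T/T0)/log2(C/T0)) − 1`, requiring `C/T0 > 1`
  (the control must grow; otherwise the transform is undefined and the
  scorer raises rather than reporting a misleading number);
- relative growth RV: `(T − T0)/(C − T0) × 100`, which can be negative
  under net cell loss;
- endpoint viability T/C as percent of control.

All replicate points (by default 3 biological × 4 technical = 12 per dose)
enter one pooled fit per scale. Per-biological-replicate fits are
available behind a flag for reproducibility analysis.

## Curve fitting

The fitted model is `f(c) = plateau + (top − plateau)/(1 + (c/mid)^h)` with
`top` fixed at the untreated response (1 on GR, 100 on percent scales).
Bounds: hill ∈ [0.1, 5]; midpoint ∈ [min dose/100, max dose × 100];
plateau ∈ [−1, 1] (GR), [−200, 100] (RV), [0, 100] (T/C). The optimizer is
bounded least squares with three deterministic starts (midpoint at the
median and the 1st/3rd log-quartiles of the tested doses), so fits are
reproducible without randomness. A sigmoid is accepted over the constant
fit only if an F-test on residual sums of squares (2 vs `n−3` df) rejects
flatness at α = 0.05 (configurable); otherwise the pair is reported as
`flat`, which is what makes GR50/GI50/IC50 legitimately missing for
non-responders while GR_aoc remains defined.

Threshold metrics use closed forms on the fitted curve — GR50 at GR = 0.5,
cytostatic dose at GR = 0, GI50 at RV = 50, IC50 at T/C = 50 — each
verified against bisection in the test suite to 1e−6 relative. GR50, GI50
and IC50 are reported NA when the root lies beyond 10× the top tested dose
or below 0.1× the lowest (extrapolated roots are not meaningful); the
cytostatic dose is reported whenever GR_inf < 0. GR_aoc is
`∫(1 − GR(c)) dlog10 c` over the tested range on the fitted curve (50
log-spaced points, trapezoidal), normalized by the log10 dose span so
screens with different ranges are comparable; the grid density and
normalization are declared conventions. IC50 is computed on T/C rather
than a day-0-corrected curve, also a declared convention.

## Cross-screen statistics

Ranking: models are ordered by GR_aoc per drug (ties broken by id, stable);
drugs are ranked within a model with average ranks for ties. Clustering of
the model × drug GR_aoc matrix uses Euclidean distance and average linkage
on the raw values, both axes, with labels sorted first so the result is
invariant to input row order.

Group comparisons use a two-sided Mann–Whitney U with a Hodges–Lehmann
shift (median of pairwise differences) and a confidence interval obtained
by inverting the U test — exactly, via the partition-count null
distribution of U, when the samples are untied and `m·n ≤ 10,000`,
otherwise with the normal approximation (continuity and tie corrected).
The exact machinery is cross-checked in the tests against exhaustive
enumeration and against values frozen from R's `wilcox.test`.

GR50–GI50 concordance is a complete-case log10–log10 Pearson correlation
with an OLS line and per-pair residuals; models are split into
faster/slower growers at the median doubling time. Because the residual
split compares clustered points, the dedicated growth-rate bias test
centers log10 of the chosen metric per drug, averages per model, and
compares slower vs faster models by Mann–Whitney — models are the
independent units. For a growth-rate-invariant metric (GR50) this test is
null-calibrated; on GI50/IC50 it exposes the systematic shift that makes
slow growers look less sensitive on endpoint scales (the algebra: a line
making `log2(C/T0)` doublings needs GR = `2^(1 − 1/log2(C/T0)) − 1` to
reach T/C = 50%, so the slower the line the deeper the required effect).

Clinical benefit ratios are new/prior PFS and TTNT, reported at one
decimal, with `meets_benchmark` tested against a 1.3 PFS-ratio criterion.
138/41 computes to 3.4 at one decimal and is reported as such.

## Loewe synergy

Two-drug checkerboards (percent-of-control responses, 0-dose margins
included) are scored against Loewe additivity: the expected response at
doses (a, b) is the effect level E with `a/A(E) + b/B(E) = 1`, where A and
B invert the Hill fits of the single-agent margins; a drug that cannot
reach E alone contributes zero. E is found by bisection over the
attainable range; combinations whose additive prediction would fall below
both plateaus are clamped to the lower plateau and flagged extrapolated.
Synergy is expected − observed (positive = more kill than additive);
`mean_synergy` averages the combination cells. Its standard error comes
from a parametric bootstrap that perturbs every cell mean by its replicate
s.e.m. and refits the margins — margin-fit error propagates to the whole
expected surface, so the per-cell s.e.m. alone would understate the
uncertainty several-fold.

## In vivo statistics

Tumor trajectories are normalized to the day-0 volume; arms are compared
by trapezoidal AUC of relative volume up to a fixed day (linear
interpolation to `t_max`, never extrapolation) with a pooled-variance
two-sided t-test (Welch behind a flag). Growth rates are log-linear
slopes. Recurrence is compared by the log-rank (Mantel–Cox) test with
censoring, via lifelines, verified against a hand-computed risk table.
Organoid→xenograft concordance is a Spearman correlation between GR_aoc
and an in vivo endpoint (default: treated-arm AUC of relative volume),
signed so perfect concordance is +1.

## Synthetic data

The generator emulates the screen design end to end: 8-point half-log
dilution from 10 µM, 4 technical × 3 biological replicates, 16 day-0 wells
on a separate plate, 16 vehicle wells per replicate, 96 h exposure, lines
with doubling times in [3, 8] d. Growth is exponential over the exposure
window (`C/T0 = 2^(96/(24·DT))`) and the treated endpoint inverts the GR
transform exactly (`T = T0·(C/T0)^log2(GR*+1)`), so in the noiseless limit
the scorer recovers truth to numerical precision. Noise is multiplicative
lognormal: cv 0.05 per well, 0.05 across day-0 wells, plus a lognormal
per-biological-replicate seeding scale (s.d. 0.10) that cancels under
per-replicate normalization, as in the real assay.

Drug truths are archetypes: inert; growth reduction (GR_inf ∈
[0.65, 0.9]); cytostatic ([0.05, 0.35]); cytotoxic ([−1, −0.3]); with
GEC50 log-uniform in [0.03, 1] µM (inside the tested ladder) and hill in
[0.8, 2.5]. The archetype bounds are chosen to sit decisively on one side
of each metric's threshold for any doubling time in [3, 8] d, so the
missing-metric pattern is predictable from truth. For one drug across a
line panel (the concordance study) GEC50 and hill are a single shared draw
and lines differ in GR_inf through a latent sensitivity, which is also what
drives the simulated in vivo response — one compound, varying depth of
response.

Synergy grids are generated Loewe-additive from true margin curves, minus
an optional synergy bonus. In vivo trajectories are exponential with
measurement noise, sampled twice weekly; recurrence times are exponential
with hazard increasing in residual end-of-treatment burden and censoring
at follow-up. Clinical durations are exponential around stated medians,
with a deterministic mode.

What the generator does not emulate: plate spatial (edge) effects,
organoid subclonal heterogeneity, drug-penetration gradients, non-Hill
dose responses, and non-exponential growth. Passing tests therefore
demonstrate correctness of the scoring and statistics under the stated
noise model, not robustness to those real-data artifacts.

## Problem sizes and numerical choices

The validation suites use deliberately compact designs: recovery runs 100
seeded 2-line × 2-drug screens (400 responsive pairs); the growth-rate
invariance study runs 100 cohorts of 8 lines (4 at DT 3 d, 4 at 8 d) × 6
shared cytotoxic truths; additivity 100 seeded 6×6 checkerboards;
concordance 200 runs of 8 coupled lines with 5 mice/arm. Degenerate
inputs fail loudly: non-growing controls, missing vehicle or day-0 wells,
fewer than 4 distinct doses, trajectories shorter than the requested AUC
window, and recurrence tables with no events all raise errors rather than
returning numbers.

## Known limitations

- Midpoints of weak partial responders (GR_inf ≥ ~0.65) are poorly
  identified at realistic noise — the likelihood is nearly flat in GEC50
  when the response span is small. Recovery guarantees are therefore
  stated for cytostatic/cytotoxic truths; weak responders still get
  well-defined GR_aoc values.
- GR values computed from noisy endpoint wells are slightly upward-biased
  in slow growers (convexity of `2^x`); the effect on GR50 is ~0.01 log10
  at default noise, an order of magnitude below the endpoint-metric bias
  it replaces.
- The exact Mann–Whitney CI is conservative at very small sample sizes
  (discrete achievable coverage), matching R's `wilcox.test` convention.
- Single-timepoint screens only; time-resolved GR variants and plate
  spatial corrections are out of scope.
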