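# Methods

## Model and assumptions

The object of study is the map from fetal biometry to estimated fetal
weight (EFW) defined by each of 29 published multi-parameter regression
formulas. For one formula, one reference dataset and one gestational week,
the biometric inputs are modelled as independent uniform random variables
on the interval between the dataset's published 10th and 90th percentile of
that parameter at that week. Uniformity deliberately weights the whole
appropriate-for-gestational-age range evenly rather than privileging any
measured population's distribution; independence is a modelling assumption
the Sobol' framework requires (see Limitations). Under it, the output
variance decomposes orthogonally (Hoeffding) and the first-, second- and
total-order Sobol' indices are well defined, dimensionless shares of
variance.

Formulas are encoded declaratively (form tag + coefficient terms) in a
packaged manifest, so coefficients are introspectable and the evaluator is
a single vectorized routine. Structural forms are `linear` (polynomial in
the biometry, grams), `log10` (10^polynomial) and `exp` (e^polynomial);
terms may carry a logarithmic factor (used by the Schild and
INTERGROWTH-21 formulas). Inputs are centimetres throughout; formulas
whose original publications report kilograms carry a ×1000 output scale.
Several coefficients in circulating transcriptions of these formulas are
corrupted (dropped minus signs or leading zeros, a collapsed fraction, an
HC/FL swap); each registry entry records in its `source` field where the
implemented coefficients deviate from common transcriptions and why. Two
entries (Shepard I, Warsof) are identical expressions as published
side-by-side in the comparative literature; both are kept so the registry
matches the canonical 29-row list. Vintzileos II is implemented exactly as
transcribed although its term-gestation output (~780 g) suggests a
transcription problem in the circulating form; no authoritative original
was available to resolve it, and the entry documents this.

## Sampling and estimators

Designs use scrambled Sobol' low-discrepancy sequences
(`scipy.stats.qmc.Sobol`): one 2d-dimensional stream is split into the two
base matrices A and B so the pair is jointly low-discrepancy, then mapped
affinely onto the bounds box. Unscrambled sequences (with the degenerate
all-zeros point skipped) are available and are the `build_design` default;
the study pipeline always scrambles, keyed by a per-(formula, week) seed
derived from the master seed via SHA-256, so that (a) runs are
deterministic, (b) subsetting formulas or datasets never perturbs other
results, and (c) two datasets with identical bounds at a week produce
identical estimates — duplicating a chart cannot manufacture
between-dataset variance.

First- and total-order variance components use the Jansen estimators

    S_i  = (V − (1/2N) Σ (f(B) − f(AB_i))²) / V
    ST_i = (1/2N) Σ (f(A) − f(AB_i))² / V

where AB_i is A with column i replaced from B. The Jansen first-order
numerator is evaluated against B (the B-side convention); the convention
is fixed here and validated against closed forms rather than inherited
from any particular software. The closed second-order component is the
classical cross-matrix estimator
`V_ij ≈ mean(f(BA_i)·f(AB_j)) − mean(f(A))·mean(f(B))`, from which the two
Jansen main effects are subtracted; it reuses the already-built cross
matrices. The total variance is the plug-in variance of the pooled A and B
outputs (2N points), using every available evaluation in the denominator.

Numerical conventions: first-order indices are clamped to [0, 1] for
reporting (raw values retained), total-order clamped below at 0,
second-order reported raw since its smallness in magnitude is itself a
finding (a clamped companion is available). A non-positive total variance
(constant model on the box) raises a degenerate-model error rather than
returning indices. Both oracles (product `k·X·Y` and additive `b·X + c·Y²`
with uniform inputs) have exact closed forms in the package and pin the
estimators in tests: at N = 2^17 the estimates agree with the closed forms
to well under 0.005.

## Bootstrap aggregation

Per-dataset index estimates for one (formula, week) are a small sample
(one value per reference chart covering that week). The mean index is
bootstrapped: datasets resampled with replacement, the mean of each
resample recorded, and the resulting distribution summarized by its median
and central 95% interval. Quantiles are inverse-ECDF order statistics (no
interpolation). Weeks 43–44 are excluded from grouping (too few charts).
Groups with a single dataset are kept and reported with zero-width CIs
rather than dropped, so sparsely covered early/late weeks remain visible.

By default all parameters and orders of one (formula, week) share the same
resample draw ("joint" mode), preserving the within-dataset correlation
between parameter indices; an "independent" per-group mode exists for
comparison. Per-group seeds derive from the master seed and the group key
over content sorted by dataset id, making every summary invariant to input
order. The default number of resamples is 10^6; tests and the synthetic
study run at 10^3–10^4, which for these group sizes changes CI endpoints
by far less than the between-dataset spread.

## Study-level statistics

Behaviour flags are computed on the bootstrap medians of the first-order
indices (the per-week summary curve), not on raw per-dataset values:

- *insignificant*: median index strictly below 0.3 at every covered week;
- *dominant*: strictly above 0.7 at every covered week;
- *crossover*: some parameter pair whose median-index difference takes
  both signs over the covered weeks (exact ties count as sign 0 and
  neither confirm nor block);
- *turning points*: strict sign changes of consecutive weekly differences
  within weeks 10–20, with zero-difference plateaus dropped before
  counting (a plateau followed by a decline is one turning point);
- *monotone after week 20*: all weekly differences strictly one-signed
  from week 20 on.

"Throughout gestation" always means: at every week where the group exists
for that formula, since week coverage differs across formulas and
datasets. Aggregate percentages are rounded to whole percents for display;
raw fractions are kept in the outputs. The per-parameter insignificance
rate is taken over the formulas containing that parameter.

The one-at-a-time perturbation analysis evaluates a formula at all-median
biometry, then with each parameter in turn at its 90th percentile,
reporting percent increases to two decimals. It complements the indices: a
local, unit-free effect size against a global variance share.

## Reference week-38 chart

The packaged `intergrowth21_week38.csv` carries 10th/50th/90th percentile
values of BPD, HC, AC and FL at gestational week 38 for the
INTERGROWTH-21st international fetal growth standards. The p50/p90 values
were reconstructed at machine precision from published EFW reference
computations on that chart (nine published EFW values over-determine the
eight unknowns; the least-squares solution reproduces all nine to < 0.1 g).
The 10th percentiles use the symmetry of the centile model
(p10 = 2·p50 − p90). First-order indices computed on these bounds
reproduce the published reference values for Hadlock III and Hadlock IV to
±0.002.

## Synthetic data generator

The generator emulates the statistical structure of a collection of
published percentile charts: per-parameter median growth curves that are
strictly increasing and saturating (logistic — a fixture choice for
guaranteed monotonicity, not a growth-model claim), symmetric 10th–90th
bands whose half-width grows linearly with week, one multiplicative and
one additive jitter per dataset and parameter (applied once per curve so
monotonicity is preserved), and per-dataset coverage windows drawn from
configurable samplers with the first two datasets pinned wide so every
mid-gestation week is covered by at least two datasets. Default magnitudes
put HC/AC in the tens of cm and BPD/FL in single digits at term, with
aggregate spreads growing severalfold from week 10 to 42 — cosmetic
defaults at realistic scales.

What the generator does **not** emulate: skewed centile bands (real charts
are asymmetric), between-parameter correlation of jitters, within-dataset
week-to-week noise, digitization error, or any real population's actual
centiles. Consequently, tests passing on synthetic studies demonstrate the
pipeline's correctness and invariances (grouping, bootstrap behaviour,
flag logic, determinism, structurally forced dominances), not the numeric
study-level percentages that real digitized charts would produce; those
depend on the charts themselves, which users can supply through the
documented CSV schema and manifest.

The planted-formula fixture inverts the additive analytic oracle: given
target first-order indices, coefficients `c_p ∝ sqrt(target_p / Var(X_p))`
produce an additive formula whose exact indices (targets normalized to sum
one) ship alongside the spec for recovery testing.

## Problem sizes

Defaults follow the study design: N = 10^6 model evaluations per
(formula, dataset, week) and 10^6 bootstrap resamples per group. The test
suite and the synthetic end-to-end study run at N = 2^10–2^17 and 500–10^4
resamples — at these sizes the estimator error (validated against the
closed forms) is already far below every tolerance asserted, and the full
29-formula × 26-dataset study completes in about a minute.

## Limitations

- Independent uniform inputs: real biometric parameters are strongly
  correlated; variance shares here answer "what if each parameter varied
  freely within its normal range", not "how do parameters co-vary in a
  population". Correlation-aware importance measures (Shapley effects,
  density-based indices) are out of scope.
- The 10th–90th truncation excludes small- and large-for-gestational-age
  fetuses; indices for those populations may differ.
- Indices are computed per integer week with no interpolation across
  weeks; datasets missing an interior week simply contribute nothing
  there.
- The percentile bootstrap undercovers slightly at very small n (few
  datasets per week); the tests assert ≥ 85% empirical coverage at n = 10
  rather than nominal 95%.
- Formula transcription risk: coefficients were cross-checked for
  plausibility (term-gestation weight corridors, worked examples) and
  corrected where provably corrupted, but two entries (Vintzileos II; the
  duplicated Shepard I/Warsof pair) could not be verified against their
  originals and are implemented as transcribed.
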