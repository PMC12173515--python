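# efwsens

Variance-based global sensitivity analysis of ultrasonic fetal-weight
estimation formulas.

Sonographers estimate fetal weight (EFW) by plugging ultrasound biometry —
biparietal diameter (BPD), head circumference (HC), abdominal circumference
(AC) and femur length (FL), all in cm — into one of dozens of published
regression formulas. Those formulas do not lean on their inputs equally,
and the balance shifts with gestational age. `efwsens` quantifies that
balance for 29 established multi-parameter formulas: it tells you, per
formula and per gestational week, what share of the EFW variance each
biometric parameter is responsible for. The intended users are researchers
in obstetric biometry and quantitative clinicians choosing or refining EFW
formulas (e.g. preferring formulas insensitive to head measurements late in
gestation, when the fetal head is hard to image).

## Method

For a formula `f(X)` with independent inputs, the Hoeffding decomposition
splits the output variance into main effects and interactions,

```
Var[f(X)] = Σᵢ Vᵢ + Σᵢ<ⱼ Vᵢⱼ + …
```

and the Sobol' indices are the normalized shares `Sᵢ = Vᵢ / Var[f(X)]`
(first order), `Sᵢⱼ = Vᵢⱼ / Var[f(X)]` (pairwise interaction), and the
total effect `STᵢ = Sᵢ + Σⱼ Sᵢⱼ + …`. For each reference dataset and
gestational week, inputs are sampled uniformly between the published 10th
and 90th percentile of each parameter for that week, using scrambled Sobol'
low-discrepancy sequences. Variance components are estimated with the
Jansen squared-difference estimators on paired design matrices
(`Sᵢ = 1 − (1/2N)Σ(f(B) − f(ABᵢ))²/V`, `STᵢ = (1/2N)Σ(f(A) − f(ABᵢ))²/V`)
and the classical cross-matrix estimator for closed second-order terms.
Per-week index estimates from many heterogeneous reference charts are then
aggregated by non-parametric bootstrap: datasets are resampled with
replacement, resample means collected, and each (formula, week, parameter)
group summarized by the median of those means with an empirical 95% CI.

On top of the indices the pipeline computes per-formula behaviour flags:
*insignificant* parameters (median first-order index < 0.3 at every covered
week), *dominant* parameters (> 0.7 throughout), importance *crossovers*
(rank reversals between parameters over gestation), turning points in weeks
10–20, and strict monotonicity after week 20 — plus study-level percentages
of formulas showing each behaviour.

## Worked example

EFW response of Hadlock III at gestational week 38, on the packaged
INTERGROWTH-21st reference chart values — one-at-a-time shifts of each
parameter from the median to its 90th percentile, then the full Sobol'
decomposition over the 10th–90th percentile box:

```python
import efwsens as e

reg = e.load_registry()                    # all 29 formulas
chart = e.load_reference_week38_chart()
spec = reg.get("hadlock_iii")

print(e.perturbation_analysis(spec, chart, 38).to_string(index=False))
b = e.bounds_for(chart, 38, spec.required_params)
r = e.compute_sobol_indices(spec, b, n_samples=2**20, scramble_seed=0)
print({p: round(v, 3) for p, v in r.first_order.items()})
```

prints

```
    formula  week parameter  efw_median_g   efw_p90_g  percent_increase
hadlock_iii    38        HC   2990.583915 3102.947809              3.76
hadlock_iii    38        AC   2990.583915 3376.140061             12.89
hadlock_iii    38        FL   2990.583915 3123.260067              4.44
{'HC': 0.076, 'AC': 0.82, 'FL': 0.104}
```

Reading: a median-biometry fetus at week 38 weighs 2990.6 g under
Hadlock III. Moving AC alone to its 90th percentile raises the estimate by
12.9%, versus ~4% for HC or FL — and the first-order indices say the same
thing globally: AC alone accounts for 82% of the EFW variance over the
physiological range, HC under 8%. HC could be mis-measured (or simply taken
from a percentile chart) with little effect on this formula's output.

A full study runs from the command line. With no real percentile charts at
hand, generate a synthetic study first:

```
efwsens simulate --n-datasets 26 --seed 1 --outdir charts/
efwsens run-all --manifest charts/manifest.yaml --outdir out/ \
    --n-samples 16384 --n-resamples 10000 --seed 1
```

which writes tidy `indices.csv`, `summaries.csv` (bootstrap medians and 95%
CIs per formula/week/parameter), `flags.csv` (per-formula behaviour) and
`metadata.json`, and prints the study-level percentages. `efwsens indices`,
`bootstrap`, `summarize` and `perturb` expose the individual stages.

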