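"""Synthetic percentile-chart studies with realistic growth structure.

Real reference charts come from heterogeneous published populations: each
gives monotonically increasing median growth curves over roughly weeks
10-42, 10th/90th bands that widen with gestation, and differing week
coverage, so that per-week cross-dataset samples vary in size.  The
generator reproduces exactly those features — logistic median curves
(monotone, saturating), linearly widening symmetric bands, per-dataset
multiplicative/additive jitter, and randomized coverage windows — without
claiming to model any real population.

It also plants additive test formulas with known analytic Sobol' indices,
for parameter-recovery testing of the estimation engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .charts import PercentileChart, ParameterBounds, write_chart_csv
from .exceptions import ValidationError
from .formulas import PARAMETERS, FormulaSpec, Term
from .sobol import _uniform_moment, derive_seed


@dataclass(frozen=True)
class LogisticCurve:
    """Median growth curve p50(w) = base + (asym - base) / (1 + exp(-rate (w - infl)))."""

    baseline_cm: float
    asymptote_cm: float
    rate_per_week: float
    inflection_week: float

    def __post_init__(self):
        if not (self.asymptote_cm > self.baseline_cm > 0):
            raise ValidationError("requires asymptote > baseline > 0")
        if self.rate_per_week <= 0:
            raise ValidationError("growth rate must be positive")

    def __call__(self, week) -> np.ndarray:
        w = np.asarray(week, dtype=float)
        return self.baseline_cm + (self.asymptote_cm - self.baseline_cm) / (
            1.0 + np.exp(-self.rate_per_week * (w - self.inflection_week))
        )


@dataclass(frozen=True)
class BandModel:
    """Symmetric half-width of the 10th-90th band, widening linearly with week."""

    halfwidth_week10_cm: float
    halfwidth_growth_per_week: float

    def __post_init__(self):
        if self.halfwidth_week10_cm <= 0 or self.halfwidth_growth_per_week <= 0:
            raise ValidationError("half-widths and their growth must be positive")

    def __call__(self, week) -> np.ndarray:
        w = np.asarray(week, dtype=float)
        return self.halfwidth_week10_cm + self.halfwidth_growth_per_week * (w - 10.0)


@dataclass
class GrowthCurveParams:
    """Defaults chosen so synthetic charts match real fetal biometry scales:

    head and abdominal circumferences in the tens of cm at term, BPD and FL
    single-digit cm, aggregate 10th-90th spreads of order 1 cm early in
    gestation growing several-fold by week 42.
    """

    curves: Mapping[str, LogisticCurve] = field(
        default_factory=lambda: {
            "BPD": LogisticCurve(0.5, 10.0, 0.16, 21.0),
            "HC": LogisticCurve(1.0, 35.5, 0.16, 22.0),
            "AC": LogisticCurve(1.0, 38.0, 0.13, 26.0),
            "FL": LogisticCurve(0.3, 8.0, 0.14, 22.0),
        }
    )
    bands: Mapping[str, BandModel] = field(
        default_factory=lambda: {
            "BPD": BandModel(0.25, 0.015),
            "HC": BandModel(0.60, 0.040),
            "AC": BandModel(0.80, 0.060),
            "FL": BandModel(0.25, 0.020),
        }
    )
    #: std dev of the per-dataset multiplicative scale jitter (log scale)
    scale_jitter: float = 0.03
    #: std dev of the per-dataset additive shift jitter, cm
    shift_jitter: float = 0.10
    #: inclusive samplers for coverage windows (start, end weeks)
    coverage_start: Tuple[int, int] = (10, 18)
    coverage_end: Tuple[int, int] = (38, 42)

    def __post_init__(self):
        for p in self.curves:
            if p not in PARAMETERS:
                raise ValidationError(f"unknown parameter {p!r}")
        lo, hi = self.coverage_start
        lo2, hi2 = self.coverage_end
        if not (10 <= lo <= hi <= lo2 <= hi2 <= 44):
            raise ValidationError("coverage windows must be ordered within [10, 44]")


def generate_chart(
    params: GrowthCurveParams,
    dataset_id: str,
    seed: int = 0,
    week_range: Tuple[int, int] = (10, 42),
) -> PercentileChart:
    """One synthetic dataset's chart over the given inclusive week range.

    The median curve is the logistic curve perturbed by a single per-dataset
    multiplicative and additive jitter per parameter (applied once, keeping
    the curve strictly increasing); p10/p90 are p50 -/+ a strictly widening
    half-width.  Deterministic per seed.
    """
    w0, w1 = week_range
    if not (10 <= w0 <= w1 <= 44):
        raise ValidationError(f"week range {week_range} outside [10, 44]")
    rng = np.random.default_rng(seed)
    weeks = np.arange(w0, w1 + 1)
    chart = PercentileChart(dataset_id=dataset_id, source_meta=f"synthetic seed={seed}")
    for p in PARAMETERS:
        scale = float(np.exp(rng.normal(0.0, params.scale_jitter)))
        shift = float(rng.normal(0.0, params.shift_jitter))
        p50 = params.curves[p](weeks) * scale + shift
        hw = params.bands[p](weeks) * scale
        p10 = p50 - hw
        p90 = p50 + hw
        if np.any(p10 <= 0):
            raise ValidationError(
                f"{dataset_id}: parameters produce non-positive 10th percentile for {p}"
            )
        for w, a, m, b in zip(weeks, p10, p50, p90):
            chart.add_record(int(w), p, float(a), float(m), float(b))
    return chart


def generate_study(
    n_datasets: int = 26,
    params: Optional[GrowthCurveParams] = None,
    master_seed: int = 0,
) -> List[PercentileChart]:
    """A heterogeneous collection of synthetic charts, one per dataset.

    Coverage windows are drawn per dataset from the configured samplers;
    the first two datasets are pinned to wide coverage so that (for
    n_datasets >= 2) every week in [14, 38] is covered by at least two
    datasets and mid-gestation bootstrap groups are never degenerate.
    Early (10-13) and late (41+) weeks end up covered by fewer datasets,
    which is what widens their confidence intervals downstream.
    """
    if n_datasets < 1:
        raise ValidationError("n_datasets must be >= 1")
    params = params or GrowthCurveParams()
    charts = []
    for k in range(n_datasets):
        seed = derive_seed("synthetic-dataset", k, master_seed=master_seed)
        rng = np.random.default_rng(seed)
        if k < 2:
            start, end = 12, 40
        else:
            start = int(rng.integers(params.coverage_start[0], params.coverage_start[1] + 1))
            end = int(rng.integers(params.coverage_end[0], params.coverage_end[1] + 1))
        charts.append(
            generate_chart(
                params, dataset_id=f"synthetic_{k:02d}", seed=seed, week_range=(start, end)
            )
        )
    return charts


def write_study(
    charts: Sequence[PercentileChart], outdir, manifest_name: str = "manifest.yaml"
) -> Path:
    """Write charts + a YAML manifest consumable by the study pipeline."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for c in charts:
        fname = f"{c.dataset_id}.csv"
        write_chart_csv(c, outdir / fname)
        entries.append(
            {
                "id": c.dataset_id,
                "path": fname,
                "source": c.source_meta or "synthetic",
                "weeks": f"{c.weeks[0]}-{c.weeks[-1]}",
            }
        )
    manifest = outdir / manifest_name
    manifest.write_text(yaml.safe_dump({"datasets": entries}, sort_keys=False))
    return manifest


def generate_planted_formula(
    target_first_order: Mapping[str, float],
    bounds: ParameterBounds | Mapping[str, Tuple[float, float]],
    name: str = "planted",
) -> Tuple[FormulaSpec, Dict[str, float]]:
    """An additive formula whose analytic first-order indices are known.

    Builds f = sum_p c_p X_p over the given uniform boxes with
    c_p proportional to sqrt(target_p / Var(X_p)); for an additive model the
    realized indices are the targets normalized to sum one.  Returns the
    spec together with the exact analytic indices for assertions.  Targets
    must lie in (0, 1) and sum to at most 1.
    """
    bmap = dict(bounds.bounds) if isinstance(bounds, ParameterBounds) else dict(bounds)
    if not target_first_order:
        raise ValidationError("at least one target index required")
    total = 0.0
    for p, t in target_first_order.items():
        if p not in bmap:
            raise ValidationError(f"bounds missing parameter {p!r}")
        if not (0.0 < t < 1.0):
            raise ValidationError(f"target for {p!r} must lie in (0, 1), got {t}")
        total += t
    if total > 1.0 + 1e-12:
        raise ValidationError(f"targets sum to {total:.4f} > 1: infeasible")

    coefs: Dict[str, float] = {}
    variances: Dict[str, float] = {}
    for p, t in target_first_order.items():
        lo, hi = bmap[p]
        var = _uniform_moment(lo, hi, 2) - _uniform_moment(lo, hi, 1) ** 2
        variances[p] = var
        coefs[p] = float(np.sqrt(t / var))
    v_total = sum(coefs[p] ** 2 * variances[p] for p in coefs)
    truth = {p: coefs[p] ** 2 * variances[p] / v_total for p in coefs}
    spec = FormulaSpec(
        name=name,
        display_name=f"{name} (planted additive)",
        form="linear",
        terms=tuple(Term(coef=coefs[p], powers={p: 1}) for p in sorted(coefs)),
        source_citation="synthetic planted-index fixture",
    )
    return spec, truth
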