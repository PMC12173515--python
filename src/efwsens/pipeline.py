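"""End-to-end study orchestration and study-level summary statistics.

A "study" runs the whole chain: percentile charts -> per-(formula, dataset,
week) Sobol' indices -> cross-dataset bootstrap summaries -> per-formula
flags (insignificant parameters, dominance, importance crossovers, turning
points, late-gestation monotonicity) -> study-level percentages.  All
randomness derives from one master seed, so a fixed configuration
reproduces its output tables byte for byte.

Thresholds follow the reporting conventions for parameter importance: a
parameter is *insignificant* in a formula when its median first-order index
stays strictly below 0.3 at every covered week, and *dominant* when it
stays strictly above 0.7 throughout.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .bootstrap import BootstrapSummary, pair_label, summarize_study
from .charts import PercentileChart, bounds_for, read_chart_csv
from .exceptions import NoDataError, ValidationError
from .formulas import FormulaRegistry, FormulaSpec, evaluate_formula, load_registry, BiometricVector
from .sobol import SobolResult, compute_sobol_indices, derive_seed

log = logging.getLogger("efwsens")

INSIGNIFICANCE_THRESHOLD = 0.3
DOMINANCE_THRESHOLD = 0.7


@dataclass
class StudyConfig:
    """Configuration of one full study run."""

    manifest: Optional[str] = None
    formulas: Optional[List[str]] = None  # default: all registry entries
    week_start: int = 10
    week_end: int = 42
    n_samples: int = 10**6
    n_resamples: int = 10**6
    ci_level: float = 0.95
    seed: int = 0
    outdir: Optional[str] = None
    insignificance_threshold: float = INSIGNIFICANCE_THRESHOLD
    dominance_threshold: float = DOMINANCE_THRESHOLD
    bootstrap_mode: str = "joint"

    def __post_init__(self):
        if not (0.0 < self.insignificance_threshold < 1.0) or not (
            0.0 < self.dominance_threshold < 1.0
        ):
            raise ValidationError("thresholds must lie in (0, 1)")
        if not (10 <= self.week_start <= self.week_end <= 44):
            raise ValidationError("week range must lie within [10, 44]")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class StudyResult:
    """Tidy outputs of a study run."""

    indices: pd.DataFrame  # one row per (formula, dataset, week, parameter, order)
    summaries: pd.DataFrame  # one row per bootstrap group
    flags: pd.DataFrame  # one row per formula
    metadata: Dict


def read_manifest(path) -> List[PercentileChart]:
    """Load every chart listed in a YAML dataset manifest."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not data or "datasets" not in data or not data["datasets"]:
        raise ValidationError(f"{path}: manifest lists no datasets")
    charts = []
    for entry in data["datasets"]:
        chart_path = Path(entry["path"])
        if not chart_path.is_absolute():
            chart_path = path.parent / chart_path
        chart = read_chart_csv(chart_path, units=entry.get("units", "cm"))
        if "source" in entry:
            chart.source_meta = str(entry["source"])
        charts.append(chart)
    return charts


# ---------------------------------------------------------------------------
# Summary statistics on weekly median-index series
# ---------------------------------------------------------------------------


def detect_insignificant(
    per_week_medians: Mapping[int, float], threshold: float = INSIGNIFICANCE_THRESHOLD
) -> bool:
    """True iff the index stays strictly below the threshold at every week."""
    if not per_week_medians:
        raise ValidationError("empty index series")
    return all(v < threshold for v in per_week_medians.values())


def detect_dominant(
    per_week_medians: Mapping[int, float], threshold: float = DOMINANCE_THRESHOLD
) -> bool:
    """True iff the index stays strictly above the threshold at every week."""
    if not per_week_medians:
        raise ValidationError("empty index series")
    return all(v > threshold for v in per_week_medians.values())


def detect_crossover(
    series_by_param: Mapping[str, Mapping[int, float]],
) -> Tuple[bool, List[Tuple[str, str]]]:
    """Detect importance-rank reversals between parameter pairs.

    A pair (p, q) crosses over when the sign of (index_p - index_q) differs
    between two covered weeks; exact ties have sign 0 and neither confirm
    nor block a crossover.  All series must share the same week grid.
    """
    params = sorted(series_by_param)
    if len(params) < 2:
        raise ValidationError("crossover detection requires >= 2 parameters")
    grids = {p: tuple(sorted(series_by_param[p])) for p in params}
    if len(set(grids.values())) != 1:
        raise ValidationError(f"mismatched week grids: {grids}")
    weeks = grids[params[0]]
    crossing = []
    for i, p in enumerate(params):
        for q in params[i + 1 :]:
            signs = {
                int(np.sign(series_by_param[p][w] - series_by_param[q][w]))
                for w in weeks
            }
            if 1 in signs and -1 in signs:
                crossing.append((p, q))
    return bool(crossing), crossing


def count_turning_points(series: Mapping[int, float]) -> int:
    """Number of interior strict sign changes in the weekly differences.

    Zero differences (plateaus) are dropped before counting, so a plateau
    followed by a decline counts as a single turning point.
    """
    if len(series) < 3:
        raise ValidationError("turning-point counting requires >= 3 weeks")
    values = [series[w] for w in sorted(series)]
    diffs = [b - a for a, b in zip(values, values[1:])]
    signs = [int(np.sign(d)) for d in diffs if d != 0]
    return sum(1 for a, b in zip(signs, signs[1:]) if a != b)


def _strictly_monotone(series: Mapping[int, float]) -> bool:
    values = [series[w] for w in sorted(series)]
    diffs = [b - a for a, b in zip(values, values[1:])]
    return bool(diffs) and (all(d > 0 for d in diffs) or all(d < 0 for d in diffs))


def compute_flags(
    summaries: Sequence[BootstrapSummary],
    insignificance_threshold: float = INSIGNIFICANCE_THRESHOLD,
    dominance_threshold: float = DOMINANCE_THRESHOLD,
    turning_point_window: Tuple[int, int] = (10, 20),
) -> pd.DataFrame:
    """Per-formula behaviour flags from bootstrap medians of first-order indices.

    Flags are computed on the median series (the quantity plotted per week),
    not on raw per-dataset indices.  "Throughout gestation" means at every
    week for which the formula has a bootstrap group.
    """
    first = [s for s in summaries if s.order == "first"]
    by_formula: Dict[str, Dict[str, Dict[int, float]]] = {}
    for s in first:
        by_formula.setdefault(s.formula_name, {}).setdefault(s.parameter, {})[
            s.week
        ] = s.median_of_means

    rows = []
    for formula in sorted(by_formula):
        series_by_param = by_formula[formula]
        params = sorted(series_by_param)
        insig = [
            p
            for p in params
            if detect_insignificant(series_by_param[p], insignificance_threshold)
        ]
        dominant = [
            p for p in params if detect_dominant(series_by_param[p], dominance_threshold)
        ]
        if len(params) >= 2:
            has_cross, pairs = detect_crossover(series_by_param)
        else:
            has_cross, pairs = False, []
        w0, w1 = turning_point_window
        turning = []
        for p in params:
            window = {w: v for w, v in series_by_param[p].items() if w0 <= w <= w1}
            if len(window) >= 3 and count_turning_points(window) > 0:
                turning.append(p)
        monotone_after = {
            p: _strictly_monotone(
                {w: v for w, v in series_by_param[p].items() if w >= 20}
            )
            for p in params
        }
        rows.append(
            {
                "formula": formula,
                "parameters": ";".join(params),
                "has_insignificant_param": bool(insig),
                "insignificant_params": ";".join(insig),
                "has_crossover": has_cross,
                "crossover_pairs": ";".join("-".join(pr) for pr in pairs),
                "dominant_params": ";".join(dominant),
                "turning_point_params_weeks_10_20": ";".join(turning),
                "strictly_monotone_after_week_20": ";".join(
                    f"{p}:{'yes' if monotone_after[p] else 'no'}" for p in params
                ),
            }
        )
    return pd.DataFrame(rows)


def aggregate_flags(flags: pd.DataFrame) -> Dict:
    """Study-level percentages over the per-formula flag table.

    Per-parameter insignificance rates are taken over the formulas that
    contain the parameter.  Display values are rounded to whole percents;
    raw fractions are retained alongside.
    """
    n = len(flags)
    if n == 0:
        return {"n_formulas": 0}
    frac_insig = float(flags["has_insignificant_param"].mean())
    frac_cross = float(flags["has_crossover"].mean())
    frac_dom = float((flags["dominant_params"] != "").mean())
    frac_turn = float((flags["turning_point_params_weeks_10_20"] != "").mean())
    per_param = {}
    for p in ("BPD", "HC", "AC", "FL"):
        containing = flags[
            flags["parameters"].str.split(";").map(lambda ps: p in ps)
        ]
        if len(containing):
            rate = float(
                containing["insignificant_params"]
                .str.split(";")
                .map(lambda ps: p in ps)
                .mean()
            )
            per_param[p] = {
                "n_formulas_with_param": int(len(containing)),
                "insignificance_rate": rate,
                "insignificance_pct": round(100 * rate),
            }
    dominant_formulas = {
        row["formula"]: row["dominant_params"]
        for _, row in flags.iterrows()
        if row["dominant_params"]
    }
    return {
        "n_formulas": int(n),
        "insignificant_param_fraction": frac_insig,
        "insignificant_param_pct": round(100 * frac_insig),
        "crossover_fraction": frac_cross,
        "crossover_pct": round(100 * frac_cross),
        "dominance_fraction": frac_dom,
        "dominance_pct": round(100 * frac_dom),
        "dominant_formulas": dominant_formulas,
        "turning_point_fraction_weeks_10_20": frac_turn,
        "turning_point_pct_weeks_10_20": round(100 * frac_turn),
        "per_parameter_insignificance": per_param,
    }


# ---------------------------------------------------------------------------
# Perturbation analysis (one-at-a-time p90 substitution)
# ---------------------------------------------------------------------------


def perturbation_analysis(
    spec: FormulaSpec, chart: PercentileChart, week: int
) -> pd.DataFrame:
    """EFW response to moving one parameter from the median to the 90th centile.

    Baseline: all required parameters at p50.  For each parameter in turn,
    that parameter is set to p90 with the rest at p50; the percent increase
    over baseline is reported to two decimals.
    """
    p50s, p90s = {}, {}
    for p in spec.required_params:
        p10, p50, p90 = chart.percentiles(week, p)
        if p50 is None:
            raise NoDataError(
                f"dataset {chart.dataset_id!r}: no median (p50) for {p} at week {week}"
            )
        p50s[p], p90s[p] = p50, p90
    kwargs = {p.lower(): v for p, v in p50s.items()}
    baseline = evaluate_formula(spec, BiometricVector(**kwargs))
    rows = []
    for p in spec.required_params:
        shifted = dict(p50s)
        shifted[p] = p90s[p]
        efw = evaluate_formula(
            spec, BiometricVector(**{q.lower(): v for q, v in shifted.items()})
        )
        rows.append(
            {
                "formula": spec.name,
                "week": week,
                "parameter": p,
                "efw_median_g": baseline,
                "efw_p90_g": efw,
                "percent_increase": round(100.0 * (efw - baseline) / baseline, 2),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tidy serialization of per-dataset results
# ---------------------------------------------------------------------------


def results_to_frame(results: Sequence[SobolResult]) -> pd.DataFrame:
    """One row per (formula, dataset, week, parameter, order) index estimate."""
    rows = []
    for r in results:
        base = {
            "formula": r.formula_name,
            "dataset_id": r.dataset_id,
            "week": r.week,
            "n_samples": r.n_samples,
            "total_variance": r.total_variance,
        }
        for p, v in r.first_order.items():
            rows.append({**base, "parameter": p, "order": "first", "index": v})
        for p, v in r.total_order.items():
            rows.append({**base, "parameter": p, "order": "total", "index": v})
        for (pi, pj), v in r.second_order.items():
            rows.append(
                {**base, "parameter": pair_label(pi, pj), "order": "second", "index": v}
            )
    cols = [
        "formula", "dataset_id", "week", "parameter", "order",
        "index", "n_samples", "total_variance",
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["formula", "dataset_id", "week", "order", "parameter"]).reset_index(
        drop=True
    )


def frame_to_results(df: pd.DataFrame) -> List[SobolResult]:
    """Rebuild minimal per-dataset results from a tidy index table."""
    results = []
    for (formula, dataset, week), grp in df.groupby(
        ["formula", "dataset_id", "week"], sort=True
    ):
        first = {
            r["parameter"]: r["index"]
            for _, r in grp[grp["order"] == "first"].iterrows()
        }
        total = {
            r["parameter"]: r["index"]
            for _, r in grp[grp["order"] == "total"].iterrows()
        }
        second = {
            tuple(r["parameter"].split("*")): r["index"]
            for _, r in grp[grp["order"] == "second"].iterrows()
        }
        results.append(
            SobolResult(
                formula_name=formula,
                dataset_id=dataset,
                week=int(week),
                param_order=tuple(sorted(first)),
                n_samples=int(grp["n_samples"].iloc[0]),
                total_variance=float(grp["total_variance"].iloc[0]),
                first_order=first,
                total_order=total,
                second_order=second,
            )
        )
    return results


def summaries_to_frame(
    summaries: Sequence[BootstrapSummary], n_samples: int
) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "formula": s.formula_name,
                "week": s.week,
                "parameter": s.parameter,
                "order": s.order,
                "n_datasets": s.n_datasets,
                "median_index": s.median_of_means,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "n_samples": n_samples,
                "n_resamples": s.n_resamples,
                "seed": s.seed,
            }
            for s in summaries
        ]
    )
    return df.sort_values(["formula", "week", "order", "parameter"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def compute_study_indices(
    charts: Sequence[PercentileChart],
    registry: FormulaRegistry,
    week_range: Tuple[int, int] = (10, 42),
    n_samples: int = 2**14,
    master_seed: int = 0,
) -> List[SobolResult]:
    """Sobol' indices for every (formula, dataset, week) with usable bounds.

    (dataset, week) pairs lacking any required parameter are skipped.  The
    scramble seed of each run derives from the master seed and the
    (formula, week) pair — not the dataset id — so results are stable under
    subsetting and two datasets with identical bounds at a week yield
    identical estimates (duplicating a chart cannot manufacture
    between-dataset variance).
    """
    results = []
    w0, w1 = week_range
    for spec in registry:
        t0 = time.perf_counter()
        n_runs = 0
        for chart in charts:
            for week in chart.weeks:
                if not (w0 <= week <= w1):
                    continue
                try:
                    bounds = bounds_for(chart, week, spec.required_params)
                except NoDataError:
                    continue
                seed = derive_seed(spec.name, week, master_seed=master_seed)
                results.append(
                    compute_sobol_indices(
                        spec,
                        bounds,
                        n_samples=n_samples,
                        scramble_seed=seed,
                        dataset_id=chart.dataset_id,
                        week=week,
                    )
                )
                n_runs += 1
        log.info(
            "indices: %-16s %3d (dataset, week) pairs in %.2fs",
            spec.name, n_runs, time.perf_counter() - t0,
        )
    return results


def run_study(
    config: StudyConfig,
    charts: Optional[Sequence[PercentileChart]] = None,
    registry: Optional[FormulaRegistry] = None,
) -> StudyResult:
    """Run the full pipeline and (optionally) write the tidy output tables.

    Outputs are deterministic functions of the configuration: identical
    configs give byte-identical ``indices.csv``, ``summaries.csv``,
    ``flags.csv`` and ``metadata.json``.
    """
    t_start = time.perf_counter()
    if charts is None:
        if config.manifest is None:
            raise ValidationError("run_study needs charts or a manifest path")
        charts = read_manifest(config.manifest)
    if registry is None:
        registry = load_registry()
    if config.formulas is not None:
        if not config.formulas:
            raise ValidationError("formula subset is empty")
        registry = registry.subset(config.formulas)

    results = compute_study_indices(
        charts,
        registry,
        week_range=(config.week_start, config.week_end),
        n_samples=config.n_samples,
        master_seed=config.seed,
    )
    t_idx = time.perf_counter()
    summaries = summarize_study(
        results,
        n_resamples=config.n_resamples,
        ci_level=config.ci_level,
        seed=config.seed,
        mode=config.bootstrap_mode,  # type: ignore[arg-type]
    )
    t_boot = time.perf_counter()
    flags = compute_flags(
        summaries,
        insignificance_threshold=config.insignificance_threshold,
        dominance_threshold=config.dominance_threshold,
    )
    metadata = {
        "package_version": _pkg_version,
        "numpy_version": np.__version__,
        # outdir is where the tables land, not part of what was computed;
        # omitting it keeps metadata identical across re-runs to new dirs
        "config": {k: v for k, v in asdict(config).items() if k != "outdir"},
        "n_datasets": len(charts),
        "n_formulas": len(registry),
        "n_results": len(results),
        "sampling": "scrambled Sobol' sequence, per-combination seeds derived from master seed",
        "aggregate": aggregate_flags(flags),
    }
    log.info(
        "study: %d index runs in %.1fs, bootstrap in %.1fs",
        len(results), t_idx - t_start, t_boot - t_idx,
    )
    result = StudyResult(
        indices=results_to_frame(results),
        summaries=summaries_to_frame(summaries, config.n_samples),
        flags=flags,
        metadata=metadata,
    )
    if config.outdir is not None:
        write_outputs(result, config.outdir)
    return result


def write_outputs(result: StudyResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.indices.to_csv(outdir / "indices.csv", index=False, float_format="%.10g")
    result.summaries.to_csv(outdir / "summaries.csv", index=False, float_format="%.10g")
    result.flags.to_csv(outdir / "flags.csv", index=False)
    (outdir / "metadata.json").write_text(
        json.dumps(result.metadata, indent=2, sort_keys=True) + "\n"
    )
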