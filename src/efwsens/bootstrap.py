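"""Non-parametric bootstrap aggregation of Sobol' indices across datasets.

Per-dataset index estimates for the same (formula, gestational week) are
treated as a small sample; resampling datasets with replacement and
averaging yields the sampling distribution of the mean index, summarized by
its empirical median and a central 95% interval (inverse-ECDF order
statistics, no interpolation).

Weeks 43 and 44 are excluded from grouping: too few reference charts cover
them for a meaningful resample.

By default all parameters and orders of one (formula, week) group share the
same dataset resample draw ("joint" mode), preserving the within-dataset
correlation between parameter indices; an "independent" per-group draw is
available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Literal, Sequence, Tuple

import numpy as np

from .exceptions import ValidationError
from .sobol import SobolResult, derive_seed

LAST_GROUPED_WEEK = 42

Order = Literal["first", "second", "total"]


def pair_label(pi: str, pj: str) -> str:
    """Canonical label for an unordered parameter pair, e.g. ``AC*BPD``."""
    return "*".join(sorted((pi, pj)))


@dataclass
class IndexGroup:
    """Per-dataset index estimates for one (formula, week, parameter, order)."""

    formula_name: str
    week: int
    parameter: str  # single parameter, or a pair label for order="second"
    order: Order
    values: List[float]
    dataset_ids: List[str]

    def __post_init__(self):
        if not self.values:
            raise ValidationError("IndexGroup requires at least one value")
        if self.week > LAST_GROUPED_WEEK:
            raise ValidationError(
                f"weeks beyond {LAST_GROUPED_WEEK} are never grouped"
            )


@dataclass
class BootstrapSummary:
    """Median of the bootstrapped mean index with its empirical 95% CI."""

    formula_name: str
    week: int
    parameter: str
    order: Order
    n_datasets: int
    n_resamples: int
    median_of_means: float
    ci_low: float
    ci_high: float
    seed: int


def group_indices(results: Iterable[SobolResult]) -> List[IndexGroup]:
    """Group per-dataset results by (formula, week <= 42, parameter, order).

    First-order values enter clamped to [0, 1] (the reported convention),
    total-order as computed, second-order raw (their smallness in magnitude
    is the quantity of interest).  Groups are sorted by dataset id, making
    downstream seeding insensitive to input order.
    """
    buckets: Dict[Tuple[str, int, str, str], List[Tuple[str, float]]] = {}

    def put(key, dataset_id, value):
        buckets.setdefault(key, []).append((dataset_id or "", float(value)))

    for r in results:
        if r.week is None or r.week > LAST_GROUPED_WEEK:
            continue
        for p, v in r.first_order.items():
            put((r.formula_name, r.week, p, "first"), r.dataset_id, v)
        for p, v in r.total_order.items():
            put((r.formula_name, r.week, p, "total"), r.dataset_id, v)
        for (pi, pj), v in r.second_order.items():
            put((r.formula_name, r.week, pair_label(pi, pj), "second"), r.dataset_id, v)

    groups = []
    for (formula, week, param, order), pairs in sorted(buckets.items()):
        pairs.sort(key=lambda t: t[0])
        groups.append(
            IndexGroup(
                formula_name=formula,
                week=week,
                parameter=param,
                order=order,  # type: ignore[arg-type]
                values=[v for _, v in pairs],
                dataset_ids=[d for d, _ in pairs],
            )
        )
    return groups


def _ecdf_quantiles(means: np.ndarray, ci_level: float) -> Tuple[float, float, float]:
    alpha = 1.0 - ci_level
    med, lo, hi = np.quantile(
        means, [0.5, alpha / 2.0, 1.0 - alpha / 2.0], method="inverted_cdf"
    )
    return float(med), float(lo), float(hi)


def bootstrap_mean(
    values: Sequence[float],
    n_resamples: int = 10**6,
    ci_level: float = 0.95,
    seed: int = 0,
    _chunk: int = 1 << 16,
) -> Tuple[float, float, float]:
    """Bootstrap the mean of ``values``; return (median, ci_low, ci_high).

    Each resample draws len(values) values with replacement and takes their
    mean; the summary statistics are inverse-ECDF quantiles of the
    ``n_resamples`` means.  Deterministic for a fixed seed.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise ValidationError("bootstrap_mean requires a non-empty sample")
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")
    if not (0.0 < ci_level < 1.0):
        raise ValidationError("ci_level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    means = np.empty(n_resamples)
    done = 0
    while done < n_resamples:
        m = min(_chunk, n_resamples - done)
        idx = rng.integers(0, n, size=(m, n))
        means[done : done + m] = values[idx].mean(axis=1)
        done += m
    return _ecdf_quantiles(means, ci_level)


def summarize_study(
    results: Iterable[SobolResult],
    n_resamples: int = 10**6,
    ci_level: float = 0.95,
    seed: int = 0,
    mode: Literal["joint", "independent"] = "joint",
    _chunk: int = 1 << 16,
) -> List[BootstrapSummary]:
    """Bootstrap every (formula, week, parameter, order) group of a study.

    ``joint`` mode draws one dataset-resample stream per (formula, week) and
    applies it to every parameter and order of that group, preserving the
    within-dataset correlation structure across parameters; ``independent``
    mode draws a separate stream per (formula, week, parameter, order).
    Sub-seeds derive from the master seed and the group key, so adding a
    formula never perturbs other groups.
    """
    groups = group_indices(results)
    by_fw: Dict[Tuple[str, int], List[IndexGroup]] = {}
    for g in groups:
        by_fw.setdefault((g.formula_name, g.week), []).append(g)

    out: List[BootstrapSummary] = []
    for (formula, week), fw_groups in sorted(by_fw.items()):
        n = len(fw_groups[0].dataset_ids)
        if mode == "joint" and any(len(g.dataset_ids) != n for g in fw_groups):
            # mixed coverage inside one (formula, week): fall back per group
            joint_here = False
        else:
            joint_here = mode == "joint"

        if joint_here:
            group_seed = derive_seed(formula, week, master_seed=seed)
            rng = np.random.default_rng(group_seed)
            arrays = [np.asarray(g.values, float) for g in fw_groups]
            means = [np.empty(n_resamples) for _ in fw_groups]
            done = 0
            while done < n_resamples:
                m = min(_chunk, n_resamples - done)
                idx = rng.integers(0, n, size=(m, n))
                for a, mm in zip(arrays, means):
                    mm[done : done + m] = a[idx].mean(axis=1)
                done += m
            for g, mm in zip(fw_groups, means):
                med, lo, hi = _ecdf_quantiles(mm, ci_level)
                out.append(
                    BootstrapSummary(
                        formula_name=g.formula_name,
                        week=g.week,
                        parameter=g.parameter,
                        order=g.order,
                        n_datasets=len(g.values),
                        n_resamples=n_resamples,
                        median_of_means=med,
                        ci_low=lo,
                        ci_high=hi,
                        seed=group_seed,
                    )
                )
        else:
            for g in fw_groups:
                group_seed = derive_seed(
                    formula, week, g.parameter, g.order, master_seed=seed
                )
                med, lo, hi = bootstrap_mean(
                    g.values, n_resamples, ci_level, seed=group_seed, _chunk=_chunk
                )
                out.append(
                    BootstrapSummary(
                        formula_name=g.formula_name,
                        week=g.week,
                        parameter=g.parameter,
                        order=g.order,
                        n_datasets=len(g.values),
                        n_resamples=n_resamples,
                        median_of_means=med,
                        ci_low=lo,
                        ci_high=hi,
                        seed=group_seed,
                    )
                )
    return out
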