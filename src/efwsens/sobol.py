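"""Variance-based Sobol' sensitivity analysis with Jansen estimators.

The engine draws a quasi-random (Sobol' low-discrepancy) design inside the
per-week biometric bounds, evaluates a fetal-weight formula on it, and
estimates first-, second- and total-order Sobol' indices.  First- and
total-order variance components use the Jansen squared-difference
estimators; the closed second-order component uses the classical
cross-matrix (Saltelli) estimator, from which the main effects are
subtracted.

Closed-form oracles for product and additive test functions with uniform
inputs are provided for validation; they are independent of the Monte Carlo
path.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import qmc

from .charts import ParameterBounds
from .exceptions import DegenerateModelError, ValidationError
from .formulas import FormulaSpec


@dataclass
class SobolDesign:
    """Paired quasi-random design matrices for Sobol' index estimation.

    ``matrix_a`` and ``matrix_b`` are independent N x d point sets inside
    the bounds box.  ``cross_ab[i]`` is A with column i taken from B (used
    by the Jansen first/total-order estimators); ``cross_ba[i]`` is B with
    column i taken from A (needed for second-order terms).
    """

    n_samples: int
    param_order: Tuple[str, ...]
    matrix_a: np.ndarray
    matrix_b: np.ndarray
    cross_ab: Tuple[np.ndarray, ...]
    cross_ba: Tuple[np.ndarray, ...]
    scramble_seed: Optional[int] = None

    @property
    def dimension(self) -> int:
        return len(self.param_order)

    def columns(self, matrix: np.ndarray) -> Dict[str, np.ndarray]:
        return {p: matrix[:, j] for j, p in enumerate(self.param_order)}


def build_design(
    bounds: ParameterBounds | Mapping[str, Tuple[float, float]],
    param_order: Optional[Sequence[str]] = None,
    n_samples: int = 2**16,
    scramble_seed: Optional[int] = None,
) -> SobolDesign:
    """Draw the A/B/cross design inside the given bounds box.

    A single 2d-dimensional Sobol' sequence supplies A (first d columns) and
    B (last d columns), preserving the joint low-discrepancy of the pair.
    With ``scramble_seed`` set, Owen scrambling keyed by the seed is applied
    (reproducible); unscrambled sequences skip the initial all-zeros point.
    Points are mapped affinely from the unit cube onto the bounds.
    """
    if isinstance(bounds, ParameterBounds):
        bmap = dict(bounds.bounds)
        if param_order is None:
            param_order = bounds.parameters
    else:
        bmap = dict(bounds)
        if param_order is None:
            param_order = tuple(bmap)
    param_order = tuple(param_order)
    if n_samples < 2:
        raise ValidationError("n_samples must be >= 2")
    lo = np.empty(len(param_order))
    hi = np.empty(len(param_order))
    for j, p in enumerate(param_order):
        if p not in bmap:
            raise ValidationError(f"bounds missing parameter {p!r}")
        lo[j], hi[j] = bmap[p]
        if not (lo[j] < hi[j]):
            raise ValidationError(f"zero-width or inverted interval for {p!r}: {bmap[p]}")
    d = len(param_order)
    sampler = qmc.Sobol(
        d=2 * d, scramble=scramble_seed is not None, seed=scramble_seed
    )
    if scramble_seed is None:
        sampler.fast_forward(1)  # drop the degenerate all-zeros point
    with warnings.catch_warnings():
        # non power-of-two sample sizes are legitimate here (tiny test designs)
        warnings.simplefilter("ignore", UserWarning)
        u = sampler.random(n_samples)
    a = lo + u[:, :d] * (hi - lo)
    b = lo + u[:, d:] * (hi - lo)
    cross_ab = []
    cross_ba = []
    for i in range(d):
        m = a.copy()
        m[:, i] = b[:, i]
        cross_ab.append(m)
        m = b.copy()
        m[:, i] = a[:, i]
        cross_ba.append(m)
    return SobolDesign(
        n_samples=n_samples,
        param_order=param_order,
        matrix_a=a,
        matrix_b=b,
        cross_ab=tuple(cross_ab),
        cross_ba=tuple(cross_ba),
        scramble_seed=scramble_seed,
    )


def _check_variance(total_variance: float):
    if not (total_variance > 0) or not np.isfinite(total_variance):
        raise DegenerateModelError(
            f"total variance must be positive and finite, got {total_variance!r} "
            "(model output is constant over the sampled box?)"
        )


def jansen_first_order(
    f_b: np.ndarray, f_ab_i: np.ndarray, total_variance: float
) -> float:
    """Jansen estimate of the first-order index S_i, clamped to [0, 1].

    S_i = (V - (1/2N) sum (f(B) - f(AB_i))^2) / V, where AB_i shares only
    column i with B, so the squared-difference term estimates V - V_i.
    """
    s = _jansen_first_order_raw(f_b, f_ab_i, total_variance)
    return float(min(1.0, max(0.0, s)))


def _jansen_first_order_raw(f_b, f_ab_i, total_variance) -> float:
    f_b = np.asarray(f_b, float)
    f_ab_i = np.asarray(f_ab_i, float)
    if f_b.shape != f_ab_i.shape:
        raise ValidationError("output vectors must have equal length")
    _check_variance(total_variance)
    vi = total_variance - 0.5 * np.mean((f_b - f_ab_i) ** 2)
    return float(vi / total_variance)


def jansen_total_order(
    f_a: np.ndarray, f_ab_i: np.ndarray, total_variance: float
) -> float:
    """Jansen estimate of the total-order index ST_i, clamped below at 0.

    ST_i = (1/2N) sum (f(A) - f(AB_i))^2 / V; A and AB_i differ only in
    column i, so the squared difference estimates the total effect of i.
    """
    f_a = np.asarray(f_a, float)
    f_ab_i = np.asarray(f_ab_i, float)
    if f_a.shape != f_ab_i.shape:
        raise ValidationError("output vectors must have equal length")
    _check_variance(total_variance)
    st = 0.5 * np.mean((f_a - f_ab_i) ** 2) / total_variance
    return float(max(0.0, st))


def second_order_index(
    f_a: np.ndarray,
    f_b: np.ndarray,
    f_ab_i: np.ndarray,
    f_ab_j: np.ndarray,
    f_ba_i: np.ndarray,
    total_variance: float,
) -> float:
    """Cross-matrix estimate of the pure second-order index S_ij.

    The closed two-factor component V_{ij}^c is estimated from the product
    of outputs on BA_i and AB_j (which share exactly columns i and j);
    subtracting the Jansen main effects V_i and V_j leaves the interaction.
    Monte Carlo noise can make the result slightly negative; the raw value
    is returned (clamp downstream for reporting).
    """
    arrays = [np.asarray(x, float) for x in (f_a, f_b, f_ab_i, f_ab_j, f_ba_i)]
    n = {a.shape for a in arrays}
    if len(n) != 1:
        raise ValidationError("output vectors must have equal length")
    f_a, f_b, f_ab_i, f_ab_j, f_ba_i = arrays
    _check_variance(total_variance)
    f0_sq = np.mean(f_a) * np.mean(f_b)
    v_ij_closed = np.mean(f_ba_i * f_ab_j) - f0_sq
    s_i = _jansen_first_order_raw(f_b, f_ab_i, total_variance)
    s_j = _jansen_first_order_raw(f_b, f_ab_j, total_variance)
    return float(v_ij_closed / total_variance - s_i - s_j)


@dataclass
class SobolResult:
    """Estimated Sobol' indices for one (formula, dataset, week) triple."""

    formula_name: str
    dataset_id: Optional[str]
    week: Optional[int]
    param_order: Tuple[str, ...]
    n_samples: int
    total_variance: float  # grams^2
    first_order: Dict[str, float]  # clamped to [0, 1]
    total_order: Dict[str, float]  # clamped below at 0
    second_order: Dict[Tuple[str, str], float]  # raw (may be slightly < 0)
    first_order_raw: Dict[str, float] = field(default_factory=dict)
    scramble_seed: Optional[int] = None

    @property
    def second_order_clamped(self) -> Dict[Tuple[str, str], float]:
        return {k: min(1.0, max(0.0, v)) for k, v in self.second_order.items()}


def compute_sobol_indices(
    spec: FormulaSpec,
    bounds: ParameterBounds | Mapping[str, Tuple[float, float]],
    n_samples: int = 2**16,
    scramble_seed: Optional[int] = None,
    dataset_id: Optional[str] = None,
    week: Optional[int] = None,
) -> SobolResult:
    """Full Sobol' analysis of one formula over one week's bounds box.

    Builds the design, evaluates the formula vectorized on every matrix,
    and applies the Jansen / cross-matrix estimators.  The total variance is
    the plug-in variance of the pooled A and B outputs (2N points).
    """
    design = build_design(
        bounds, param_order=spec.required_params, n_samples=n_samples,
        scramble_seed=scramble_seed,
    )
    f_a = spec.evaluate_arrays(design.columns(design.matrix_a))
    f_b = spec.evaluate_arrays(design.columns(design.matrix_b))
    f_ab = [spec.evaluate_arrays(design.columns(m)) for m in design.cross_ab]
    total_variance = float(np.var(np.concatenate([f_a, f_b])))
    _check_variance(total_variance)

    first, first_raw, total = {}, {}, {}
    for i, p in enumerate(design.param_order):
        raw = _jansen_first_order_raw(f_b, f_ab[i], total_variance)
        first_raw[p] = raw
        first[p] = float(min(1.0, max(0.0, raw)))
        total[p] = jansen_total_order(f_a, f_ab[i], total_variance)

    second = {}
    if design.dimension >= 2:
        f_ba = [spec.evaluate_arrays(design.columns(m)) for m in design.cross_ba]
        for i, j in combinations(range(design.dimension), 2):
            pi, pj = design.param_order[i], design.param_order[j]
            second[(pi, pj)] = second_order_index(
                f_a, f_b, f_ab[i], f_ab[j], f_ba[i], total_variance
            )
    if week is None and isinstance(bounds, ParameterBounds):
        week = bounds.week
    return SobolResult(
        formula_name=spec.name,
        dataset_id=dataset_id,
        week=week,
        param_order=design.param_order,
        n_samples=n_samples,
        total_variance=total_variance,
        first_order=first,
        total_order=total,
        second_order=second,
        first_order_raw=first_raw,
        scramble_seed=scramble_seed,
    )


def derive_seed(*key_parts, master_seed: int = 0) -> int:
    """Stable sub-seed (< 2^31) from a master seed and a hashable key.

    Uses a SHA-256 digest of the repr of the key so that adding or removing
    unrelated (formula, dataset, week) combinations never perturbs others.
    """
    payload = repr((int(master_seed),) + tuple(key_parts)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# Closed-form oracles (uniform inputs), for estimator validation
# ---------------------------------------------------------------------------


def _uniform_moment(lo: float, hi: float, n: int) -> float:
    """E[X^n] for X ~ U(lo, hi)."""
    if not (lo < hi):
        raise ValidationError(f"degenerate interval ({lo}, {hi})")
    return (hi ** (n + 1) - lo ** (n + 1)) / ((n + 1) * (hi - lo))


@dataclass(frozen=True)
class AnalyticIndices:
    """Exact Sobol' indices of a two-factor test function."""

    variance: float
    s_x: float
    s_y: float
    s_xy: float
    st_x: float
    st_y: float


def analytic_indices_product(
    k: float, x_bounds: Tuple[float, float], y_bounds: Tuple[float, float]
) -> AnalyticIndices:
    """Exact indices of f(X, Y) = k * X * Y with independent uniforms.

    V_x = k^2 mu_y^2 Var(X), V_y = k^2 mu_x^2 Var(Y),
    V_xy = k^2 Var(X) Var(Y), Var(f) = k^2 (E[X^2]E[Y^2] - mu_x^2 mu_y^2).
    Indices are invariant to k (it cancels in the ratio).
    """
    if k == 0:
        raise ValidationError("k must be nonzero (constant model)")
    mx, m2x = _uniform_moment(*x_bounds, 1), _uniform_moment(*x_bounds, 2)
    my, m2y = _uniform_moment(*y_bounds, 1), _uniform_moment(*y_bounds, 2)
    vx, vy = m2x - mx**2, m2y - my**2
    v_x = my**2 * vx
    v_y = mx**2 * vy
    v_xy = vx * vy
    var = m2x * m2y - mx**2 * my**2  # == v_x + v_y + v_xy
    return AnalyticIndices(
        variance=k**2 * var,
        s_x=v_x / var,
        s_y=v_y / var,
        s_xy=v_xy / var,
        st_x=(v_x + v_xy) / var,
        st_y=(v_y + v_xy) / var,
    )


def analytic_indices_additive(
    b: float,
    c: float,
    x_bounds: Tuple[float, float],
    y_bounds: Tuple[float, float],
) -> AnalyticIndices:
    """Exact indices of the additive f(X, Y) = b*X + c*Y^2 (uniform inputs).

    V_x = b^2 Var(X); V_y = c^2 (E[Y^4] - E[Y^2]^2); no interaction, so
    S_xy = 0 and total-order equals first-order exactly.
    """
    mx, m2x = _uniform_moment(*x_bounds, 1), _uniform_moment(*x_bounds, 2)
    m2y, m4y = _uniform_moment(*y_bounds, 2), _uniform_moment(*y_bounds, 4)
    v_x = b**2 * (m2x - mx**2)
    v_y = c**2 * (m4y - m2y**2)
    var = v_x + v_y
    if var == 0:
        raise ValidationError("b and c cannot both be zero (constant model)")
    return AnalyticIndices(
        variance=var,
        s_x=v_x / var,
        s_y=v_y / var,
        s_xy=0.0,
        st_x=v_x / var,
        st_y=v_y / var,
    )
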