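"""Sobol' design construction, Jansen estimators, closed-form oracle checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from efwsens import (
    analytic_indices_additive,
    analytic_indices_product,
    build_design,
    compute_sobol_indices,
    jansen_first_order,
    jansen_total_order,
    second_order_index,
)
from efwsens.exceptions import DegenerateModelError, ValidationError
from efwsens.formulas import FormulaSpec, Term


def make_spec(name, terms, form="linear"):
    return FormulaSpec(name=name, display_name=name, form=form, terms=tuple(terms))


PRODUCT = make_spec("product", [Term(1.0, {"AC": 1, "FL": 1})])
ADDITIVE = make_spec("additive", [Term(2.0, {"AC": 1}), Term(1.0, {"FL": 2})])
UNIT_BOX = {"AC": (0.0, 1.0), "FL": (0.0, 1.0)}


class TestDesign:
    def test_points_within_bounds_and_distinct(self):
        d = build_design({"AC": (0.0, 1.0)}, n_samples=4)
        pts = d.matrix_a[:, 0]
        assert np.all((pts >= 0) & (pts <= 1))
        assert len(np.unique(pts)) == 4

    def test_affine_mapping_containment(self):
        d = build_design({"AC": (26.0, 36.0)}, n_samples=64, scramble_seed=3)
        for m in (d.matrix_a, d.matrix_b) + d.cross_ab + d.cross_ba:
            assert m.min() >= 26.0 and m.max() <= 36.0

    def test_cross_matrices_differ_in_exactly_one_column(self):
        d = build_design(
            {"BPD": (8.0, 10.0), "AC": (26.0, 36.0), "FL": (6.0, 8.0)},
            n_samples=32, scramble_seed=1,
        )
        for i in range(d.dimension):
            same_ab = d.cross_ab[i] == d.matrix_a
            assert not same_ab[:, i].any()
            assert same_ab[:, [j for j in range(d.dimension) if j != i]].all()
            assert (d.cross_ab[i][:, i] == d.matrix_b[:, i]).all()
            assert (d.cross_ba[i][:, i] == d.matrix_a[:, i]).all()

    def test_same_seed_identical_design(self):
        d1 = build_design(UNIT_BOX, n_samples=128, scramble_seed=42)
        d2 = build_design(UNIT_BOX, n_samples=128, scramble_seed=42)
        assert (d1.matrix_a == d2.matrix_a).all() and (d1.matrix_b == d2.matrix_b).all()

    def test_zero_width_interval_rejected(self):
        with pytest.raises(ValidationError):
            build_design({"AC": (5.0, 5.0)}, n_samples=8)


class TestJansenEstimators:
    def test_first_order_zero_mean_square_difference_gives_one(self):
        f = np.array([1.0, 2.0, 3.0])
        assert jansen_first_order(f, f, float(np.var(f))) == 1.0

    def test_first_order_hand_arithmetic(self):
        # (V - (1/2N) * sum((1-1)^2 + (3-1)^2)) / V with N=2, V=1
        assert jansen_first_order([1.0, 3.0], [1.0, 1.0], 1.0) == 0.0

    def test_total_order_inactive_parameter_is_zero(self):
        f = np.array([1.0, 2.0, 3.0])
        assert jansen_total_order(f, f, float(np.var(f))) == 0.0

    def test_degenerate_variance_rejected(self):
        with pytest.raises(DegenerateModelError):
            jansen_first_order([1.0, 1.0], [1.0, 1.0], 0.0)

    def test_constant_model_raises_degenerate(self):
        const = make_spec("const", [Term(0.0, {"AC": 1}), Term(0.0, {"FL": 1}), Term(5.0, {})])
        with pytest.raises(DegenerateModelError):
            compute_sobol_indices(const, UNIT_BOX, n_samples=64, scramble_seed=0)


class TestOracleAgreement:
    """Monte Carlo estimates against exact closed forms for known functions."""

    def test_product_first_order_close_at_2e14(self):
        r = compute_sobol_indices(PRODUCT, UNIT_BOX, n_samples=2**14, scramble_seed=7)
        exact = analytic_indices_product(1.0, (0, 1), (0, 1))
        assert r.first_order["AC"] == pytest.approx(exact.s_x, abs=0.02)
        assert r.first_order["FL"] == pytest.approx(exact.s_y, abs=0.02)
        assert r.total_order["AC"] == pytest.approx(exact.st_x, abs=0.02)

    def test_product_all_orders_tight_at_2e17(self):
        r = compute_sobol_indices(PRODUCT, UNIT_BOX, n_samples=2**17, scramble_seed=11)
        exact = analytic_indices_product(1.0, (0, 1), (0, 1))
        assert r.first_order["AC"] == pytest.approx(exact.s_x, abs=0.005)
        assert r.first_order["FL"] == pytest.approx(exact.s_y, abs=0.005)
        assert r.second_order[("AC", "FL")] == pytest.approx(exact.s_xy, abs=0.005)
        assert r.total_order["AC"] == pytest.approx(exact.st_x, abs=0.005)
        assert r.total_order["FL"] == pytest.approx(exact.st_y, abs=0.005)

    def test_additive_oracle_recovered(self):
        r = compute_sobol_indices(ADDITIVE, UNIT_BOX, n_samples=2**16, scramble_seed=3)
        exact = analytic_indices_additive(2.0, 1.0, (0, 1), (0, 1))
        assert exact.s_x == pytest.approx(15 / 19)
        assert r.first_order["AC"] == pytest.approx(exact.s_x, abs=0.01)
        assert r.first_order["FL"] == pytest.approx(exact.s_y, abs=0.01)
        # additive: no interaction, total equals first order
        assert abs(r.second_order[("AC", "FL")]) < 0.01
        assert r.total_order["AC"] - r.first_order["AC"] == pytest.approx(0.0, abs=0.01)

    def test_structural_zero_vs_nonzero_interaction(self):
        # f(X, Y, Z) = X + Y*Z: the (X, Y) pair has no interaction, (Y, Z) does
        spec = make_spec("mixed", [Term(1.0, {"BPD": 1}), Term(1.0, {"AC": 1, "FL": 1})])
        box = {"BPD": (0.0, 1.0), "AC": (0.0, 1.0), "FL": (0.0, 1.0)}
        r = compute_sobol_indices(spec, box, n_samples=2**15, scramble_seed=9)
        assert abs(r.second_order[("BPD", "AC")]) < 0.01
        assert r.second_order[("AC", "FL")] > 0.05

    def test_single_active_dimension(self):
        # second parameter enters with zero weight: all variance is the first's
        spec = make_spec("solo", [Term(1.0, {"AC": 1}), Term(1e-12, {"FL": 1})])
        r = compute_sobol_indices(spec, UNIT_BOX, n_samples=2**12, scramble_seed=2)
        assert r.first_order["AC"] == pytest.approx(1.0, abs=0.01)
        assert r.total_order["AC"] == pytest.approx(1.0, abs=0.01)
        assert r.first_order["FL"] == pytest.approx(0.0, abs=0.01)


class TestInvariants:
    def test_normalization_two_parameter(self):
        r = compute_sobol_indices(PRODUCT, UNIT_BOX, n_samples=2**16, scramble_seed=5)
        total = sum(r.first_order.values()) + sum(r.second_order.values())
        assert total == pytest.approx(1.0, abs=0.01)

    def test_total_at_least_first_order(self, registry, week38_chart):
        from efwsens import bounds_for

        spec = registry.get("hadlock_iii")
        b = bounds_for(week38_chart, 38, spec.required_params)
        r = compute_sobol_indices(spec, b, n_samples=2**13, scramble_seed=4)
        for p in spec.required_params:
            assert r.total_order[p] >= r.first_order[p] - 0.01
        assert sum(r.first_order.values()) <= 1.01

    def test_scale_equivariance(self):
        scaled = make_spec("scaled", [Term(137.0, {"AC": 1, "FL": 1})])
        r1 = compute_sobol_indices(PRODUCT, UNIT_BOX, n_samples=2**13, scramble_seed=6)
        r2 = compute_sobol_indices(scaled, UNIT_BOX, n_samples=2**13, scramble_seed=6)
        for p in ("AC", "FL"):
            assert r1.first_order[p] == pytest.approx(r2.first_order[p], abs=1e-9)
            assert r1.total_order[p] == pytest.approx(r2.total_order[p], abs=1e-9)

    def test_determinism(self):
        r1 = compute_sobol_indices(PRODUCT, UNIT_BOX, n_samples=2**12, scramble_seed=8)
        r2 = compute_sobol_indices(PRODUCT, UNIT_BOX, n_samples=2**12, scramble_seed=8)
        assert r1.first_order == r2.first_order
        assert r1.second_order == r2.second_order
        assert r1.total_variance == r2.total_variance


bounds_st = st.tuples(
    st.floats(0.1, 50, allow_nan=False), st.floats(0.5, 20, allow_nan=False)
).map(lambda t: (t[0], t[0] + t[1]))


class TestAnalyticOracles:
    @settings(derandomize=True, max_examples=50)
    @given(k=st.floats(0.01, 100), xb=bounds_st, yb=bounds_st)
    def test_product_indices_invariant_to_k_and_normalized(self, k, xb, yb):
        a = analytic_indices_product(k, xb, yb)
        b = analytic_indices_product(1.0, xb, yb)
        assert a.s_x == pytest.approx(b.s_x, rel=1e-9)
        assert a.s_xy == pytest.approx(b.s_xy, rel=1e-9)
        assert a.s_x + a.s_y + a.s_xy == pytest.approx(1.0, rel=1e-9)
        assert a.st_x == pytest.approx(a.s_x + a.s_xy, rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(b=st.floats(0.1, 10), c=st.floats(0.1, 10), xb=bounds_st, yb=bounds_st)
    def test_additive_indices_sum_to_one(self, b, c, xb, yb):
        a = analytic_indices_additive(b, c, xb, yb)
        assert a.s_x + a.s_y == pytest.approx(1.0, rel=1e-9)
        assert a.s_xy == 0.0

    def test_product_exact_values_unit_square(self):
        a = analytic_indices_product(1.0, (0, 1), (0, 1))
        assert a.variance == pytest.approx(7 / 144)
        assert a.s_x == pytest.approx(3 / 7)
        assert a.s_xy == pytest.approx(1 / 7)

    def test_additive_c_zero_single_term(self):
        a = analytic_indices_additive(2.0, 0.0, (0, 1), (0, 1))
        assert a.s_x == 1.0

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValidationError):
            analytic_indices_product(1.0, (1.0, 1.0), (0, 1))
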