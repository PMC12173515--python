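"""Bootstrap aggregation: enumeration oracles, grouping rules, coverage."""

import numpy as np
import pytest

from efwsens import bootstrap_mean, group_indices, summarize_study
from efwsens.bootstrap import IndexGroup
from efwsens.exceptions import ValidationError
from efwsens.sobol import SobolResult


def fake_result(formula="f", dataset="d0", week=20, first=None, total=None, second=None):
    first = first or {"AC": 0.7, "BPD": 0.3}
    return SobolResult(
        formula_name=formula,
        dataset_id=dataset,
        week=week,
        param_order=tuple(sorted(first)),
        n_samples=64,
        total_variance=1.0,
        first_order=first,
        total_order=total or dict(first),
        second_order=second or {("AC", "BPD"): 0.001},
    )


class TestBootstrapMean:
    def test_degenerate_constant_sample(self):
        med, lo, hi = bootstrap_mean([0.4, 0.4, 0.4], n_resamples=1000, seed=1)
        assert (med, lo, hi) == pytest.approx((0.4, 0.4, 0.4), abs=1e-12)
        assert med == lo == hi

    def test_two_point_enumeration_oracle(self):
        # resamples of (0, 1) have means 0, 0.5, 1 with probabilities 1/4, 1/2, 1/4
        med, lo, hi = bootstrap_mean([0.0, 1.0], n_resamples=10**5, seed=2)
        assert med == 0.5
        assert lo == 0.0 and hi == 1.0

    def test_single_value_zero_width(self):
        med, lo, hi = bootstrap_mean([0.37], n_resamples=500, seed=3)
        assert med == lo == hi == 0.37

    def test_same_seed_identical(self):
        a = bootstrap_mean([0.1, 0.5, 0.9], n_resamples=2000, seed=7)
        b = bootstrap_mean([0.1, 0.5, 0.9], n_resamples=2000, seed=7)
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_mean([], n_resamples=10, seed=0)

    def test_median_between_min_and_max(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, size=7)
        med, lo, hi = bootstrap_mean(values, n_resamples=5000, seed=5)
        assert values.min() <= lo <= med <= hi <= values.max()

    def test_ci_coverage_on_iid_groups(self):
        # percentile bootstrap on n=10 normal samples: >= 85% coverage of the
        # true mean over 500 replicates (small-n undercoverage allowed for)
        rng = np.random.default_rng(42)
        true_mean, hits = 0.5, 0
        reps = 500
        for k in range(reps):
            sample = rng.normal(true_mean, 0.1, size=10)
            _, lo, hi = bootstrap_mean(sample, n_resamples=2000, seed=k)
            hits += lo <= true_mean <= hi
        assert hits / reps >= 0.85


class TestGrouping:
    def test_counts_datasets_covering_the_week(self):
        results = [fake_result(dataset=f"d{i}") for i in range(3)]
        groups = group_indices(results)
        first_ac = [g for g in groups if g.order == "first" and g.parameter == "AC"]
        assert len(first_ac) == 1 and len(first_ac[0].values) == 3

    def test_weeks_43_44_excluded(self):
        results = [fake_result(week=42), fake_result(week=43), fake_result(week=44)]
        groups = group_indices(results)
        assert {g.week for g in groups} == {42}

    def test_limited_coverage_contributes_nothing_elsewhere(self):
        results = [fake_result(dataset="wide", week=40), fake_result(dataset="narrow", week=20)]
        by_week = {g.week: g for g in group_indices(results) if g.parameter == "AC" and g.order == "first"}
        assert by_week[40].dataset_ids == ["wide"]
        assert by_week[20].dataset_ids == ["narrow"]

    def test_group_requires_values(self):
        with pytest.raises(ValidationError):
            IndexGroup("f", 20, "AC", "first", values=[], dataset_ids=[])


class TestSummarizeStudy:
    def test_identical_results_give_zero_width_cis(self):
        results = [fake_result(dataset=f"d{i}") for i in range(5)]
        for s in summarize_study(results, n_resamples=2000, seed=1):
            assert s.ci_low == s.median_of_means == s.ci_high

    def test_single_dataset_zero_width(self):
        summaries = summarize_study([fake_result()], n_resamples=100, seed=1)
        s = next(x for x in summaries if x.parameter == "AC" and x.order == "first")
        assert s.median_of_means == 0.7 and s.ci_low == s.ci_high == 0.7

    def test_permutation_invariance(self):
        results = [
            fake_result(dataset=d, first={"AC": v, "BPD": 1 - v})
            for d, v in [("a", 0.6), ("b", 0.7), ("c", 0.8)]
        ]
        fwd = summarize_study(results, n_resamples=3000, seed=9)
        rev = summarize_study(list(reversed(results)), n_resamples=3000, seed=9)
        key = lambda s: (s.formula_name, s.week, s.order, s.parameter)
        for a, b in zip(sorted(fwd, key=key), sorted(rev, key=key)):
            assert (a.median_of_means, a.ci_low, a.ci_high) == (
                b.median_of_means, b.ci_low, b.ci_high)

    @pytest.mark.parametrize("mode", ["joint", "independent"])
    def test_ci_narrows_with_more_datasets(self, mode):
        rng = np.random.default_rng(17)

        def study(n):
            return [
                fake_result(dataset=f"d{i:02d}", first={"AC": 0.7 + rng.normal(0, 0.05), "BPD": 0.3})
                for i in range(n)
            ]

        def width(results):
            s = next(
                x for x in summarize_study(results, n_resamples=4000, seed=3, mode=mode)
                if x.parameter == "AC" and x.order == "first"
            )
            return s.ci_high - s.ci_low

        assert width(study(24)) < width(study(3))

    def test_median_of_means_within_value_range(self):
        rng = np.random.default_rng(8)
        results = [
            fake_result(dataset=f"d{i}", first={"AC": float(v), "BPD": 0.2})
            for i, v in enumerate(rng.uniform(0.3, 0.9, size=6))
        ]
        values = [r.first_order["AC"] for r in results]
        s = next(
            x for x in summarize_study(results, n_resamples=2000, seed=2)
            if x.parameter == "AC" and x.order == "first"
        )
        assert min(values) <= s.median_of_means <= max(values)
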