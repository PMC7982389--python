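import math

import numpy as np
import pandas as pd
import pytest

from potbench.evaluation import (
    aggregate_global,
    compare_methods,
    compute_metrics,
    flag_difficult_classes,
    mean_potency_baseline,
    per_class_metrics,
    wilcoxon_one_sided,
)
from potbench.models.nn import masked_mse_loss


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([6.0, 7.0, 8.0])
        m = compute_metrics(y, y)
        assert m.mae == m.medae == m.mse == 0.0

    def test_hand_arithmetic(self):
        m = compute_metrics(np.array([7.0, 8.0]), np.array([7.5, 8.5]))
        assert m.mae == pytest.approx(0.5)
        assert m.mse == pytest.approx(0.25)
        assert m.r == pytest.approx(1.0)

    def test_median_absolute_error(self):
        m = compute_metrics(np.array([1.0, 2.0, 3.0]), np.array([1.1, 2.2, 3.9]))
        assert m.medae == pytest.approx(0.2)

    def test_zero_variance_r_flagged_undefined(self):
        m = compute_metrics(np.array([7.0, 7.0]), np.array([6.0, 8.0]))
        assert not m.r_defined and math.isnan(m.r)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([]), np.array([]))

    def test_agrees_with_brute_force_on_random_inputs(self):
        """All metrics (and the masked loss) match naive loop implementations."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(2, 40))
            y = rng.normal(7, 1, n)
            yh = y + rng.normal(0, 0.5, n)
            m = compute_metrics(y, yh)
            abs_err = sorted(abs(a - b) for a, b in zip(y, yh))
            assert m.mae == pytest.approx(sum(abs_err) / n, abs=1e-10)
            assert m.mse == pytest.approx(sum((a - b) ** 2 for a, b in zip(y, yh)) / n, abs=1e-10)
            mid = n // 2
            med = abs_err[mid] if n % 2 else (abs_err[mid - 1] + abs_err[mid]) / 2
            assert m.medae == pytest.approx(med, abs=1e-10)
            if m.r_defined:
                my, mh = sum(y) / n, sum(yh) / n
                num = sum((a - my) * (b - mh) for a, b in zip(y, yh))
                den = math.sqrt(sum((a - my) ** 2 for a in y) * sum((b - mh) ** 2 for b in yh))
                assert m.r == pytest.approx(num / den, abs=1e-10)
            # masked loss vs explicit loop on a random mask
            mask = rng.random(n) < 0.6
            if mask.any():
                loss = masked_mse_loss(yh[None, :], y[None, :], mask[None, :])
                brute = sum((a - b) ** 2 for a, b, k in zip(y, yh, mask) if k) / mask.sum()
                assert loss == pytest.approx(brute, abs=1e-10)


class TestCompareMethods:
    def test_identical_all_indistinguishable(self):
        vals = {f"t{i}": 0.5 for i in range(10)}
        row = compare_methods(vals, dict(vals))
        assert (row.pct_a_better, row.pct_b_better, row.pct_indistinguishable) == (0, 0, 100)

    def test_boundary_difference_inclusive(self):
        a, b = {"t": 0.5}, {"t": 0.6}
        with pytest.raises(ValueError):
            compare_methods(a, {"u": 0.6})  # mismatched classes
        row = compare_methods(a, b)
        assert row.pct_a_better == 100.0
        strict = compare_methods(a, b, inclusive=False)
        assert strict.pct_a_better == 0.0

    def test_counting_example(self):
        a, b = {}, {}
        for i in range(3):
            a[f"w{i}"], b[f"w{i}"] = 0.4, 0.6  # A better by 0.2
        a["l0"], b["l0"] = 0.6, 0.4           # B better by 0.2
        for i in range(6):
            a[f"n{i}"], b[f"n{i}"] = 0.50, 0.53  # within 0.05
        row = compare_methods(a, b)
        assert (row.pct_a_better, row.pct_b_better, row.pct_indistinguishable) == (30, 10, 60)

    def test_correlation_direction(self):
        a, b = {"t": 0.8, "u": 0.5}, {"t": 0.6, "u": 0.5}
        row = compare_methods(a, b, kind="correlation")
        assert row.pct_a_better == 50.0 and row.pct_b_better == 0.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        a = {f"t{i}": float(rng.uniform(0.3, 1.0)) for i in range(37)}
        b = {k: float(v + rng.normal(0, 0.2)) for k, v in a.items()}
        row = compare_methods(a, b)
        assert row.pct_a_better + row.pct_b_better + row.pct_indistinguishable == pytest.approx(100)


class TestFlagDifficultClasses:
    def test_worked_example_population_sigma(self):
        errors = {f"c{i}": e for i, e in enumerate([0.5, 0.5, 0.5, 0.5, 2.0])}
        out = flag_difficult_classes(errors, ddof=0)
        by_id = {s.class_id: s for s in out}
        assert by_id["c4"].mu == pytest.approx(0.8)
        assert by_id["c4"].sigma == pytest.approx(0.6)
        assert by_id["c4"].threshold == pytest.approx(2.0)
        assert by_id["c4"].difficult  # boundary e == mu + 2*sigma is inclusive
        assert not any(by_id[f"c{i}"].difficult for i in range(4))

    def test_all_equal_errors_flagged_suitable(self):
        out = flag_difficult_classes({"a": 0.5, "b": 0.5, "c": 0.5})
        assert not any(s.difficult for s in out)

    def test_single_outlier_among_tight_values(self):
        rng = np.random.default_rng(9)
        errors = {f"c{i}": float(rng.normal(0.5, 0.01)) for i in range(50)}
        errors["outlier"] = 3.0
        out = flag_difficult_classes(errors)
        flagged = [s.class_id for s in out if s.difficult]
        assert flagged == ["outlier"]

    def test_requires_three_classes(self):
        with pytest.raises(ValueError):
            flag_difficult_classes({"a": 1.0, "b": 2.0})

    def test_tail_fraction_approaches_normal_mass(self):
        """On Gaussian class errors the flagged fraction matches P(Z >= 2)."""
        rng = np.random.default_rng(7)
        errors = {f"c{i}": float(e) for i, e in enumerate(rng.normal(0.6, 0.15, 10_000))}
        out = flag_difficult_classes(errors)
        frac = sum(s.difficult for s in out) / len(out)
        from scipy.stats import norm
        assert abs(frac - norm.sf(2.0)) < 0.01


class TestWilcoxon:
    def test_identical_groups_near_half(self):
        g = [0.1, 0.2, 0.3, 0.4, 0.5]
        assert wilcoxon_one_sided(g, list(g)) >= 0.4

    def test_extreme_separation_exact_enumeration(self):
        p = wilcoxon_one_sided([-1.0, -1.1, -1.2, -1.3, -1.4], [1.0, 1.1, 1.2, 1.3, 1.4])
        assert p == pytest.approx(1 / math.comb(10, 5), rel=1e-9)

    def test_shifted_distributions_significant(self):
        rng = np.random.default_rng(5)
        sig = 0
        for _ in range(20):
            g1 = rng.normal(-2.0, 1.0, 100)
            g2 = rng.normal(0.0, 1.0, 100)
            sig += wilcoxon_one_sided(g1, g2) < 1e-4
        assert sig >= 19

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_one_sided([], [1.0])


class TestBaseline:
    def test_per_task_mean_arithmetic(self):
        test = pd.DataFrame(
            [("c", "t", 7.0)], columns=["compound_id", "target_id", "y"]
        )
        out = mean_potency_baseline({"t": [6.0, 8.0]}, test)
        assert out.y_hat.tolist() == [7.0]
        assert np.mean(np.abs(out.y - out.y_hat)) == 0.0

    def test_global_vs_per_task_on_distinct_ranges(self):
        """Tasks with distinct dynamic ranges: the per-task mean wins."""
        train = {"lo": [6.0, 6.0], "hi": [9.0, 9.0]}
        test = pd.DataFrame(
            [("a", "lo", 6.0), ("b", "hi", 9.0)],
            columns=["compound_id", "target_id", "y"],
        )
        per_task = mean_potency_baseline(train, test, mode="per_task")
        global_ = mean_potency_baseline(train, test, mode="global")
        assert np.all(global_.y_hat == 7.5)
        assert np.mean(np.abs(per_task.y - per_task.y_hat)) == 0.0
        assert np.mean(np.abs(global_.y - global_.y_hat)) == 1.5

    def test_unlabeled_task_skipped_with_warning(self):
        test = pd.DataFrame(
            [("c", "t", 7.0), ("c", "u", 8.0)],
            columns=["compound_id", "target_id", "y"],
        )
        with pytest.warns(UserWarning, match="'u'"):
            out = mean_potency_baseline({"t": [7.0]}, test)
        assert out.target_id.tolist() == ["t"]


class TestAggregateGlobal:
    def test_two_values(self):
        mean, sd = aggregate_global([0.4, 0.6])
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(np.std([0.4, 0.6], ddof=1))

    def test_repeated_value_zero_sd(self):
        assert aggregate_global([0.3, 0.3, 0.3])[1] == 0.0

    def test_permutation_invariant(self):
        vals = [0.2, 0.9, 0.4, 0.7]
        assert aggregate_global(vals) == aggregate_global(vals[::-1])


def test_per_class_metrics_table():
    preds = pd.DataFrame(
        [
            ("a", "t1", 7.0, 7.5), ("b", "t1", 8.0, 8.5),
            ("a", "t2", 6.0, 6.0), ("b", "t2", 9.0, 9.0),
        ],
        columns=["compound_id", "target_id", "y", "y_hat"],
    )
    table = per_class_metrics(preds)
    assert table.loc["t1", "mae"] == pytest.approx(0.5)
    assert table.loc["t2", "mse"] == 0.0
    assert table.loc["t2", "r"] == pytest.approx(1.0)
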