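import math

import numpy as np
import pytest

from skylinecheck.coalescent_sim import make_scenario
from skylinecheck.skyline_log import draw_size_change_ratio
from skylinecheck.validation import (
    BENCHMARK_CONFUSION,
    ConfusionCounts,
    matthews_cc,
    run_validation,
    surrogate_skyline,
)


def brute_force_mcc(tp, tn, fn, fp):
    """MCC as the Pearson correlation of the 2x2 indicator table, computed
    from raw per-item vectors — an independent route to the same number."""
    truth = np.array([1] * (tp + fp) + [0] * (tn + fn))
    pred = np.array([1] * tp + [0] * fp + [0] * tn + [1] * fn)
    if truth.std() == 0 or pred.std() == 0:
        return 0.0
    return float(np.corrcoef(truth, pred)[0, 1])


class TestMatthewsCC:
    def test_benchmark_worked_examples(self):
        assert matthews_cc(ConfusionCounts(567, 139, 261, 33)) == pytest.approx(
            0.38, abs=0.005
        )
        assert matthews_cc(ConfusionCounts(264, 144, 56, 36)) == pytest.approx(
            0.61, abs=0.005
        )

    def test_perfect_classification(self):
        assert matthews_cc(ConfusionCounts(tp=10, tn=10, fn=0, fp=0)) == 1.0

    def test_zero_marginal_returns_zero(self):
        assert matthews_cc(ConfusionCounts(tp=5, tn=0, fn=0, fp=5)) == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            matthews_cc(ConfusionCounts(0, 0, 0, 0))

    def test_agrees_with_brute_force_on_random_tables(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            tp, tn, fn, fp = (int(x) for x in rng.integers(0, 40, size=4))
            if tp + tn + fn + fp == 0:
                continue
            counts = ConfusionCounts(tp, tn, fn, fp)
            assert matthews_cc(counts) == pytest.approx(
                brute_force_mcc(tp, tn, fn, fp), abs=1e-9
            )

    def test_invariant_under_class_swap(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            tp, tn, fn, fp = (int(x) for x in rng.integers(1, 40, size=4))
            a = matthews_cc(ConfusionCounts(tp, tn, fn, fp))
            b = matthews_cc(ConfusionCounts(tn, tp, fp, fn))
            assert a == pytest.approx(b, abs=1e-12)


class TestBenchmarkTable:
    def test_count_columns_are_internally_consistent(self):
        """Per sampling group every threshold row covers the same runs:
        one-population totals (tp+fp) and two-population totals (tn+fn)."""
        for group, n_one, n_two in (("combined", 600, 400), ("10", 300, 200), ("50", 300, 200)):
            for alpha in (0.01, 0.025, 0.05, 0.1):
                c = BENCHMARK_CONFUSION[(group, alpha)]
                assert c.n_onepop == n_one
                assert c.n_twopop == n_two

    def test_combined_rows_are_the_group_sums(self):
        for alpha in (0.01, 0.025, 0.05, 0.1):
            c10 = BENCHMARK_CONFUSION[("10", alpha)]
            c50 = BENCHMARK_CONFUSION[("50", alpha)]
            cc = BENCHMARK_CONFUSION[("combined", alpha)]
            assert (cc.tp, cc.tn, cc.fn, cc.fp) == (
                c10.tp + c50.tp, c10.tn + c50.tn, c10.fn + c50.fn, c10.fp + c50.fp
            )


class TestSurrogateSkyline:
    def test_constant_noiseless_chain_forces_unit_ratio(self):
        rng = np.random.default_rng(0)
        trace = surrogate_skyline(make_scenario("constant"), 0.0, rng)
        assert np.all(trace.lower == trace.upper)
        assert draw_size_change_ratio(trace, rng).ratio == pytest.approx(1.0)

    def test_expansion_noiseless_ratio_is_exact(self):
        rng = np.random.default_rng(0)
        trace = surrogate_skyline(make_scenario("expansion"), 0.0, rng)
        assert draw_size_change_ratio(trace, rng).ratio == pytest.approx(0.1)

    def test_twopop_census_trajectory_halves_the_ratio(self):
        rng = np.random.default_rng(0)
        trace = surrogate_skyline(make_scenario("twopop_deep"), 0.0, rng)
        assert draw_size_change_ratio(trace, rng).ratio == pytest.approx(0.5)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            surrogate_skyline(make_scenario("constant"), -0.1, np.random.default_rng(0))

    def test_noisy_ratio_distribution_brackets_truth(self):
        """With noise_cv=0.2 the central 95% of drawn ratios covers the
        scenario's true R."""
        scenario = make_scenario("expansion")
        rng = np.random.default_rng(2)
        ratios = np.array(
            [
                draw_size_change_ratio(surrogate_skyline(scenario, 0.2, rng), rng).ratio
                for _ in range(10_000)
            ]
        )
        lo, hi = np.percentile(ratios, [2.5, 97.5])
        assert lo < scenario.ratio < hi

    def test_rows_respect_band_ordering(self):
        rng = np.random.default_rng(3)
        trace = surrogate_skyline(make_scenario("bottleneck"), 0.4, rng)
        assert np.all(trace.lower <= trace.median)
        assert np.all(trace.median <= trace.upper)


class TestRunValidation:
    def test_single_rep_noiseless_is_deterministic(self):
        a = run_validation(reps=1, noise_cv=0.0, seed=5, n_sim=20)
        b = run_validation(reps=1, noise_cv=0.0, seed=5, n_sim=20)
        for key in a.p_values:
            np.testing.assert_array_equal(a.p_values[key], b.p_values[key])

    def test_report_shapes_and_ranges(self):
        report = run_validation(reps=4, seed=3, n_sim=20, ns=(10,))
        assert set(report.p_values) == {
            (label, 10)
            for label in (
                "constant", "expansion", "bottleneck", "twopop_shallow", "twopop_deep"
            )
        }
        for p in report.p_values.values():
            assert p.shape == (4,)
            assert np.all((0 <= p) & (p <= 1))
        for alpha in report.alphas:
            c = report.confusion(alpha)
            assert c.n_onepop == 12
            assert c.n_twopop == 8
            assert -1.0 <= report.mcc(alpha) <= 1.0

    def test_tsv_roundtrip(self, tmp_path):
        report = run_validation(reps=2, seed=1, n_sim=10, ns=(10,))
        out = tmp_path / "report.tsv"
        report.to_tsv(out)
        text = out.read_text()
        assert "POOLED" in text and "rejection_rate" in text

    def test_cells_reproducible_in_isolation(self):
        """A cell rerun alone (restricted scenario/n lists) matches the same
        cell from the full study — replicate streams are independent."""
        full = run_validation(reps=3, seed=11, n_sim=10)
        alone = run_validation(reps=3, seed=11, n_sim=10, scenarios=("expansion",), ns=(50,))
        np.testing.assert_array_equal(
            full.p_values[("expansion", 50)], alone.p_values[("expansion", 50)]
        )
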