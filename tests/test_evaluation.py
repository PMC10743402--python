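"""Metric formulas, ROC AUC, box-plot summaries and threshold sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from construct_otof import (
    ConfusionCounts,
    class_score_distribution,
    confusion_at_threshold,
    metrics_from_counts,
    roc_auc,
    threshold_report,
)

# published benchmark confusion counts (method, tp, tn, fp, fn, ba, acc)
BENCHMARK_ROWS = [
    ("ConStruct_RF", 76, 162, 15, 17, 0.866, 0.881),
    ("MetaLR", 72, 173, 4, 21, 0.876, 0.907),
    ("MutationAssessor", 77, 161, 16, 16, 0.869, 0.881),
    ("MVP", 91, 64, 105, 2, 0.679, 0.592),
]


class TestMetrics:
    @pytest.mark.parametrize("name,tp,tn,fp,fn,ba,acc", BENCHMARK_ROWS)
    def test_benchmark_rows_recovered_to_3dp(self, name, tp, tn, fp, fn, ba, acc):
        report = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn))
        assert round(report.balanced_accuracy, 3) == ba
        assert round(report.accuracy, 3) == acc

    def test_perfect_classifier(self):
        report = metrics_from_counts(ConfusionCounts(10, 10, 0, 0))
        assert (report.sensitivity, report.specificity) == (1.0, 1.0)
        assert (report.balanced_accuracy, report.accuracy) == (1.0, 1.0)

    def test_ba_identity_holds(self):
        report = metrics_from_counts(ConfusionCounts(30, 40, 10, 20))
        assert report.balanced_accuracy == (report.sensitivity + report.specificity) / 2
        assert report.accuracy == 70 / 100

    def test_ba_invariant_to_rate_swap(self):
        # swapping the class-conditional rates (transposing tp/fn with tn/fp)
        # leaves BA unchanged — guards against per-class column transposition
        a = metrics_from_counts(ConfusionCounts(76, 162, 15, 17))
        b = metrics_from_counts(ConfusionCounts(162, 76, 17, 15))
        assert a.balanced_accuracy == pytest.approx(b.balanced_accuracy)

    def test_empty_class_undefined_not_zero(self):
        report = metrics_from_counts(ConfusionCounts(0, 5, 3, 0))
        assert report.sensitivity is None
        assert report.balanced_accuracy is None
        assert report.accuracy == 5 / 8

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestConfusionAtThreshold:
    def test_simple(self):
        counts = confusion_at_threshold([0.9, 0.1], [1, 0], 0.5)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (1, 1, 0, 0)

    def test_strict_inequality_at_one(self):
        counts = confusion_at_threshold([1.0, 1.0], [1, 0], 1.0)
        assert counts.tp == 0 and counts.fp == 0

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(21)
        probs = rng.uniform(0, 1, 50)
        labels = rng.integers(0, 2, 50)
        for t in (0.0, 0.25, 0.5, 0.85):
            counts = confusion_at_threshold(probs, labels, t)
            tp = sum(1 for p, y in zip(probs, labels) if p > t and y == 1)
            tn = sum(1 for p, y in zip(probs, labels) if p <= t and y == 0)
            fp = sum(1 for p, y in zip(probs, labels) if p > t and y == 0)
            fn = sum(1 for p, y in zip(probs, labels) if p <= t and y == 1)
            assert (counts.tp, counts.tn, counts.fp, counts.fn) == (tp, tn, fp, fn)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_at_threshold([0.5], [1, 0], 0.5)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(30)
        probs = rng.uniform(0, 1, 30)
        probs[rng.integers(0, 30, 5)] = 0.5  # inject ties
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]  # both classes present
        pos = probs[labels == 1]
        neg = probs[labels == 0]
        wins = sum(1.0 for p in pos for q in neg if p > q)
        ties = sum(0.5 for p in pos for q in neg if p == q)
        oracle = (wins + ties) / (len(pos) * len(neg))
        assert roc_auc(probs, labels) == pytest.approx(oracle)

    def test_flip_symmetry(self):
        rng = np.random.default_rng(31)
        probs = rng.uniform(0, 1, 40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        assert roc_auc(1 - probs, 1 - labels) == pytest.approx(roc_auc(probs, labels))

    def test_single_class_refused(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestScoreDistribution:
    def test_degenerate_class_has_no_outliers(self):
        dist = class_score_distribution([0.6] * 4 + [0.2, 0.3], [1, 1, 1, 1, 0, 0])
        path = dist["pathogenic"]
        assert path.iqr == 0.0
        assert path.mild_outliers == [] and path.extreme_outliers == []

    def test_point_on_fence_is_not_an_outlier(self):
        # values 1..9 plus a point exactly at Q3 + 1.5*IQR
        base = np.arange(1.0, 10.0)
        q1, q3 = np.percentile(base, [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
        values = np.append(base, fence) / fence  # scale into [0,1]
        labels = np.ones(len(values), dtype=int)
        labels = np.append(labels, 0)
        values = np.append(values, 0.1)
        dist = class_score_distribution(values, labels)["pathogenic"]
        assert dist.mild_outliers == [] and dist.extreme_outliers == []

    def test_injected_extreme_point_flagged(self):
        rng = np.random.default_rng(40)
        vals = rng.uniform(0.4, 0.6, 30)
        q1, q3 = np.percentile(vals, [25, 75])
        extreme = q3 + 3.5 * (q3 - q1)
        values = np.concatenate([vals, [extreme], [0.1, 0.2]])
        labels = np.array([1] * 31 + [0, 0])
        dist = class_score_distribution(values, labels)["pathogenic"]
        assert dist.extreme_outliers == [pytest.approx(extreme)]

    def test_whiskers_bound_the_bulk(self):
        rng = np.random.default_rng(41)
        probs = np.concatenate([rng.uniform(0.6, 1.0, 40), rng.uniform(0.0, 0.3, 60)])
        labels = np.array([1] * 40 + [0] * 60)
        dist = class_score_distribution(probs, labels)
        assert dist["pathogenic"].whisker_low >= dist["pathogenic"].minimum
        assert dist["benign"].whisker_high <= dist["benign"].maximum
        assert dist["pathogenic"].whisker_low > dist["benign"].whisker_high

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            class_score_distribution([0.5, 0.6], [1, 1])


class TestThresholdReport:
    def _fixture_40_predicted_5_fp(self):
        """40 scores above 0.85, of which 5 belong to benign variants."""
        probs = np.concatenate(
            [
                np.linspace(0.86, 0.99, 35),  # true positives at t=0.85
                np.full(5, 0.90),  # false positives
                np.linspace(0.05, 0.60, 60),  # below threshold
            ]
        )
        labels = np.array([1] * 35 + [0] * 5 + [0] * 50 + [1] * 10)
        return probs, labels

    def test_fp_share_worked_example(self):
        probs, labels = self._fixture_40_predicted_5_fp()
        sweep = threshold_report(probs, labels, [0.85])
        row = sweep.rows[0]
        assert row.n_predicted_positive == 40
        assert row.counts.fp == 5
        assert row.fp_share_pct == pytest.approx(12.5)

    def test_share_undefined_above_max_probability(self):
        sweep = threshold_report([0.2, 0.4], [1, 0], [0.9])
        assert sweep.rows[0].n_predicted_positive == 0
        assert sweep.rows[0].fp_share_pct is None

    def test_monotone_sweep(self):
        rng = np.random.default_rng(50)
        probs = rng.uniform(0, 1, 200)
        labels = rng.integers(0, 2, 200)
        sweep = threshold_report(probs, labels, np.linspace(0, 1, 21))
        for a, b in zip(sweep.rows, sweep.rows[1:]):
            assert b.counts.tp <= a.counts.tp
            assert b.counts.fp <= a.counts.fp

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            threshold_report([0.5], [1], [1.5])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_tp_fp_never_increase_with_threshold(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.uniform(0, 1, 50)
        labels = rng.integers(0, 2, 50)
        lo = confusion_at_threshold(probs, labels, 0.3)
        hi = confusion_at_threshold(probs, labels, 0.7)
        assert hi.tp <= lo.tp and hi.fp <= lo.fp
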