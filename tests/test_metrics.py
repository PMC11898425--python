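"""Confusion counting and the four evaluation metrics, cross-checked
against scikit-learn and hand arithmetic."""

import numpy as np
import pytest
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from scramblenet import (
    ConfusionCounts,
    MetricsError,
    compute_metrics,
    confusion_from_predictions,
    format_table,
    read_metrics_csv,
    results_table,
    write_metrics_csv,
)


class TestConfusion:
    def test_perfect_predictions(self):
        y = ["yes"] * 10 + ["no"] * 10
        c = confusion_from_predictions(y, y)
        assert (c.tp, c.fp, c.fn, c.tn) == (10, 0, 0, 10)

    def test_all_predicted_positive(self):
        y = ["yes"] * 10 + ["no"] * 10
        c = confusion_from_predictions(y, ["yes"] * 20)
        assert (c.tp, c.fp, c.fn, c.tn) == (10, 10, 0, 0)

    def test_hand_counted_five_pairs(self):
        true = ["yes", "yes", "no", "no", "yes"]
        pred = ["yes", "no", "no", "yes", "yes"]
        c = confusion_from_predictions(true, pred)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(MetricsError, match="length"):
            confusion_from_predictions(["yes"], ["yes", "no"])

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(MetricsError):
            confusion_from_predictions(["yes", "no", "maybe"], ["yes", "no", "no"])

    def test_negative_counts_rejected(self):
        with pytest.raises(MetricsError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)

    def test_fuzz_against_sklearn_recount(self):
        rng = np.random.default_rng(0)
        labels = np.array(["no", "yes"])
        for _ in range(200):
            n = int(rng.integers(2, 60))
            true = labels[rng.integers(0, 2, n)]
            pred = labels[rng.integers(0, 2, n)]
            if len(np.unique(true)) + len(np.unique(pred)) < 3:
                continue
            c = confusion_from_predictions(true, pred)
            ref = confusion_matrix(true, pred, labels=["yes", "no"])
            assert (c.tp, c.fn, c.fp, c.tn) == (
                ref[0, 0], ref[0, 1], ref[1, 0], ref[1, 1],
            )


class TestComputeMetrics:
    def test_hand_worked_example(self):
        rep = compute_metrics(ConfusionCounts(90, 10, 5, 95))
        assert rep.accuracy == pytest.approx(0.925)
        assert rep.precision == pytest.approx(0.900)
        assert rep.recall == pytest.approx(90 / 95)
        assert rep.f1 == pytest.approx(2 * 0.9 * (90 / 95) / (0.9 + 90 / 95))

    def test_fully_symmetric_counts_give_half_everywhere(self):
        rep = compute_metrics(ConfusionCounts(25, 25, 25, 25))
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1) == (0.5,) * 4

    def test_zero_denominator_flagged_not_silent(self):
        rep = compute_metrics(ConfusionCounts(0, 0, 5, 95))
        assert rep.recall == 0.0
        assert rep.precision == 0.0
        assert "precision" in rep.degenerate

    def test_empty_confusion_rejected(self):
        with pytest.raises(MetricsError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_f1_is_harmonic_mean_in_positive_mode(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            tp, fp, fn, tn = rng.integers(1, 50, 4)
            rep = compute_metrics(ConfusionCounts(int(tp), int(fp), int(fn), int(tn)))
            harmonic = 2 * rep.precision * rep.recall / (rep.precision + rep.recall)
            assert rep.f1 == pytest.approx(harmonic)
            assert min(rep.precision, rep.recall) <= rep.f1 <= max(rep.precision, rep.recall)

    def test_accuracy_recount_fuzz(self):
        rng = np.random.default_rng(2)
        labels = np.array(["no", "yes"])
        for _ in range(100):
            true = labels[rng.integers(0, 2, 40)]
            pred = labels[rng.integers(0, 2, 40)]
            if "yes" not in true and "yes" not in pred:
                continue
            c = confusion_from_predictions(true, pred)
            rep = compute_metrics(c)
            assert rep.accuracy == pytest.approx(np.mean(true == pred))

    def test_macro_mode_matches_sklearn(self):
        true = np.array(["yes", "yes", "no", "no", "yes", "no", "yes"])
        pred = np.array(["yes", "no", "no", "yes", "yes", "no", "no"])
        c = confusion_from_predictions(true, pred)
        rep = compute_metrics(c, mode="macro")
        p, r, f, _ = precision_recall_fscore_support(
            true, pred, average="macro", zero_division=0
        )
        assert rep.precision == pytest.approx(p)
        assert rep.recall == pytest.approx(r)
        assert rep.f1 == pytest.approx(f)

    def test_weighted_mode_matches_sklearn(self):
        true = np.array(["yes"] * 8 + ["no"] * 3)
        pred = np.array(["yes"] * 6 + ["no"] * 2 + ["yes", "no", "no"])
        c = confusion_from_predictions(true, pred)
        rep = compute_metrics(c, mode="weighted")
        p, r, f, _ = precision_recall_fscore_support(
            true, pred, average="weighted", zero_division=0
        )
        assert rep.precision == pytest.approx(p)
        assert rep.recall == pytest.approx(r)
        assert rep.f1 == pytest.approx(f)

    def test_macro_metrics_invariant_under_class_swap(self):
        c = ConfusionCounts(12, 5, 7, 30)
        a = compute_metrics(c, mode="macro")
        b = compute_metrics(c.swapped(), mode="macro")
        assert a.precision == pytest.approx(b.precision)
        assert a.recall == pytest.approx(b.recall)
        assert a.f1 == pytest.approx(b.f1)
        assert a.accuracy == pytest.approx(b.accuracy)


class TestResultsTable:
    def test_half_metrics_format_as_fifty(self):
        rep = compute_metrics(ConfusionCounts(25, 25, 25, 25))
        text = format_table(results_table([("model-a", "baker", rep)]))
        assert text.count("50.00") == 4

    def test_csv_round_trip_is_lossless(self, tmp_path):
        rep = compute_metrics(ConfusionCounts(90, 10, 5, 95))
        table = results_table([("m", "arnold", rep)])
        path = tmp_path / "metrics.csv"
        write_metrics_csv(table, path)
        back = read_metrics_csv(path)
        for col in ("accuracy", "precision", "recall", "f1"):
            assert back[col][0] == table[col][0]

    def test_sort_by_descending_accuracy(self):
        low = compute_metrics(ConfusionCounts(10, 10, 10, 10))
        high = compute_metrics(ConfusionCounts(90, 10, 5, 95))
        table = results_table([("low", "none", low), ("high", "none", high)], sort=True)
        assert list(table["model"]) == ["high", "low"]

    def test_empty_rows_rejected(self):
        with pytest.raises(MetricsError):
            results_table([])
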