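"""Confusion-matrix construction and the four binary evaluation metrics.

Standard definitions with tumor ("yes") as the positive class:

    accuracy  = (TP + TN) / (TP + FP + FN + TN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

A zero denominator in precision or recall is reported as 0 together with an
explicit degeneracy flag (never silently).  Besides the positive-class
scores, macro (unweighted mean over both classes taken as positive) and
support-weighted averages are available, since published binary results do
not always state which averaging they used.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MetricsError",
    "ConfusionCounts",
    "MetricsReport",
    "confusion_from_predictions",
    "compute_metrics",
    "results_table",
    "format_table",
    "write_metrics_csv",
    "read_metrics_csv",
]


class MetricsError(ValueError):
    """Invalid labels or degenerate confusion input."""


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN counts with tumor ("yes") as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise MetricsError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swapped(self) -> "ConfusionCounts":
        """The same predictions with the positive class swapped."""
        return ConfusionCounts(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, precision, recall and F1 as proportions in [0, 1].

    ``mode`` records the averaging ("positive", "macro" or "weighted");
    ``degenerate`` lists any scores whose denominator was zero and were
    reported as 0 by convention.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    mode: str
    n: int
    degenerate: tuple = ()

    def as_percent(self) -> dict:
        return {
            "accuracy": 100.0 * self.accuracy,
            "precision": 100.0 * self.precision,
            "recall": 100.0 * self.recall,
            "f1": 100.0 * self.f1,
        }


def confusion_from_predictions(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    positive: str = "yes",
) -> ConfusionCounts:
    """Count TP/FP/FN/TN from paired label sequences.

    TP: actual positive, predicted positive; FP: actual negative,
    predicted positive; FN: actual positive, predicted negative;
    TN: actual negative, predicted negative.
    """
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise MetricsError(
            f"label sequences have different lengths: {t.shape[0]} vs {p.shape[0]}"
        )
    if t.size == 0:
        raise MetricsError("cannot build a confusion matrix from zero examples")
    seen = set(np.unique(t).tolist()) | set(np.unique(p).tolist())
    if positive not in seen and t.size > 0:
        raise MetricsError(f"positive class {positive!r} absent from labels {sorted(seen)}")
    if len(seen) > 2:
        raise MetricsError(f"expected a binary label set, got {sorted(seen)}")
    tpos = t == positive
    ppos = p == positive
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)),
        fp=int(np.sum(~tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
    )


def _prf(tp: int, fp: int, fn: int):
    """(precision, recall, f1, degenerate-flags) for one positive class."""
    flags = []
    if tp + fp == 0:
        precision = 0.0
        flags.append("precision")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        flags.append("recall")
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1 = 0.0
        flags.append("f1")
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f1, flags


def compute_metrics(c: ConfusionCounts, mode: str = "positive") -> MetricsReport:
    """Evaluate the four metrics on a confusion matrix.

    mode "positive": scores for the tumor class only (F1 is then exactly the
    harmonic mean of the reported precision and recall).  mode "macro":
    unweighted mean of the two per-class scores.  mode "weighted": mean
    weighted by true class support.
    """
    if c.total == 0:
        raise MetricsError("empty confusion matrix")
    accuracy = (c.tp + c.tn) / c.total
    pos = _prf(c.tp, c.fp, c.fn)
    if mode == "positive":
        precision, recall, f1, flags = pos
        return MetricsReport(accuracy, precision, recall, f1, mode, c.total, tuple(flags))
    neg = _prf(c.tn, c.fn, c.fp)  # negative class as positive
    if mode == "macro":
        weights = (0.5, 0.5)
    elif mode == "weighted":
        support_pos = c.tp + c.fn
        support_neg = c.tn + c.fp
        weights = (support_pos / c.total, support_neg / c.total)
    else:
        raise MetricsError(f"unknown averaging mode {mode!r}")
    precision = weights[0] * pos[0] + weights[1] * neg[0]
    recall = weights[0] * pos[1] + weights[1] * neg[1]
    f1 = weights[0] * pos[2] + weights[1] * neg[2]
    flags = tuple(sorted(set(pos[3]) | set(neg[3])))
    return MetricsReport(accuracy, precision, recall, f1, mode, c.total, flags)


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["model", "cipher", "mode", "n", "accuracy", "precision", "recall", "f1"]


def results_table(
    rows: Sequence[tuple], sort: bool = False
) -> pd.DataFrame:
    """Assemble (model name, cipher, MetricsReport) rows into a DataFrame.

    Proportions are kept at full precision; use :func:`format_table` for the
    2-decimal percentage presentation and :func:`write_metrics_csv` for the
    lossless CSV.  With ``sort=True`` rows are ordered by descending
    accuracy.
    """
    if len(rows) == 0:
        raise MetricsError("results table needs at least one row")
    data = []
    for model, cipher, report in rows:
        data.append(
            {
                "model": model,
                "cipher": cipher,
                "mode": report.mode,
                "n": report.n,
                "accuracy": report.accuracy,
                "precision": report.precision,
                "recall": report.recall,
                "f1": report.f1,
            }
        )
    table = pd.DataFrame(data, columns=_CSV_COLUMNS)
    if sort:
        table = table.sort_values("accuracy", ascending=False, kind="stable")
        table = table.reset_index(drop=True)
    return table


def format_table(table: pd.DataFrame) -> str:
    """Human-readable percentage table (2 decimals), Tables-style layout."""
    disp = pd.DataFrame(
        {
            "Algorithm": table["model"],
            "Cipher": table["cipher"],
            "Accuracy (%)": (100 * table["accuracy"]).map("{:.2f}".format),
            "Precision (%)": (100 * table["precision"]).map("{:.2f}".format),
            "Recall (%)": (100 * table["recall"]).map("{:.2f}".format),
            "F-Score (%)": (100 * table["f1"]).map("{:.2f}".format),
        }
    )
    buf = io.StringIO()
    disp.to_string(buf, index=False)
    return buf.getvalue()


def write_metrics_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Lossless CSV: shortest-repr floats, parsed back with round-trip
    precision by :func:`read_metrics_csv`."""
    table.to_csv(path, index=False)


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
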