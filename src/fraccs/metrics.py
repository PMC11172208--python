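"""Confusion-matrix accounting and the six binary-classification metrics.

Accuracy, precision, specificity, sensitivity (recall), F1 and Matthews
correlation coefficient, computed from the 2×2 table with the disease class
(e.g. glaucoma) as positive. Degenerate tables (a zero denominator) yield
NaN for the affected metric rather than raising, since tiny synthetic
fixtures routinely produce them. Percent formatting rounds to two decimals
to match conventional reporting; raw fractions are kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: column order used by the tabular report writer
REPORT_COLUMNS = ("Acc", "Pre", "F1 Score", "Spe", "Sen", "Mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion table must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Six metrics as fractions (MCC in [-1, 1]); NaN marks undefined."""

    accuracy: float
    precision: float
    specificity: float
    sensitivity: float
    f1: float
    mcc: float

    def as_percent(self, decimals: int = 2) -> dict[str, float]:
        """Metrics on the 0–100 scale, rounded (MCC ×100 as well)."""
        vals = (self.accuracy, self.precision, self.f1, self.specificity,
                self.sensitivity, self.mcc)
        return {
            name: round(100.0 * v, decimals) if math.isfinite(v) else float("nan")
            for name, v in zip(REPORT_COLUMNS, vals)
        }

    def to_frame(self, label: str = "") -> pd.DataFrame:
        row = self.as_percent()
        frame = pd.DataFrame([row], columns=list(REPORT_COLUMNS))
        if label:
            frame.insert(0, "Feature Selection", label)
        return frame


def confusion_counts(y_true, y_pred, positive_label=1) -> ConfusionCounts:
    """Tally the 2×2 table, treating ``positive_label`` as the disease class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
    t = y_true == positive_label
    p = y_pred == positive_label
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """Evaluate the six metrics from counts.

      Acc = (TP+TN) / (TP+TN+FP+FN)
      Pre = TP / (TP+FP)
      Spc = TN / (TN+FP)
      Sen = TP / (TP+FN)
      F1  = 2·Pre·Sen / (Pre+Sen)
      MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    """
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    acc = _ratio(tp + tn, c.total)
    pre = _ratio(tp, tp + fp)
    spc = _ratio(tn, tn + fp)
    sen = _ratio(tp, tp + fn)
    f1 = (
        _ratio(2.0 * pre * sen, pre + sen)
        if math.isfinite(pre) and math.isfinite(sen)
        else float("nan")
    )
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den)
    return MetricReport(
        accuracy=acc, precision=pre, specificity=spc, sensitivity=sen, f1=f1, mcc=mcc
    )


def write_report(reports: dict[str, MetricReport], path) -> None:
    """Write a delimited table, one row per method, in the standard order."""
    frames = [rep.to_frame(label) for label, rep in reports.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
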