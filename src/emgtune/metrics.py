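"""Per-class one-vs-rest evaluation metrics.

Overall accuracy is correct/total over all windows. For each movement
class, TP/TN/FP/FN are tallied one-vs-rest and yield

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)          (true positive rate)
    specificity = TN / (TN + FP)          (true negative rate)

Zero-denominator metrics are reported as missing (None), never coerced
to 0, so averages are not silently deflated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class ClassMetrics:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None


def confusion(true_labels, predicted_labels, class_id) -> ConfusionCounts:
    """One-vs-rest counts treating ``class_id`` as the positive class."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    tpos = t == class_id
    ppos = p == class_id
    return ConfusionCounts(
        TP=int(np.sum(tpos & ppos)),
        TN=int(np.sum(~tpos & ~ppos)),
        FP=int(np.sum(~tpos & ppos)),
        FN=int(np.sum(tpos & ~ppos)),
    )


def _ratio(num, den):
    return num / den if den > 0 else None


def metrics_from_counts(c: ConfusionCounts) -> ClassMetrics:
    return ClassMetrics(
        accuracy=_ratio(c.TP + c.TN, c.total),
        sensitivity=_ratio(c.TP, c.TP + c.FN),
        specificity=_ratio(c.TN, c.TN + c.FP),
    )


def overall_accuracy(true_labels, predicted_labels) -> float:
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    return float(np.mean(t == p))


def multiclass_report(true_labels, predicted_labels, n_classes: int) -> dict:
    """Overall accuracy plus per-class one-vs-rest sensitivity/specificity."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if np.any((t < 1) | (t > n_classes)):
        raise ValueError(f"true labels must lie in 1..{n_classes}")
    per_class = {}
    for k in range(1, n_classes + 1):
        per_class[k] = metrics_from_counts(confusion(t, p, k))
    return {"overall_accuracy": overall_accuracy(t, p), "per_class": per_class}


def _pct(v):
    return "n/a" if v is None else f"{100.0 * v:.1f}"


def format_report(report: dict) -> str:
    """Human-readable table, percentages with one decimal."""
    lines = [f"Overall accuracy: {_pct(report['overall_accuracy'])}%"]
    lines.append(f"{'Class':>5}  {'Sens (%)':>8}  {'Spec (%)':>8}")
    for k, m in report["per_class"].items():
        lines.append(f"{k:>5}  {_pct(m.sensitivity):>8}  {_pct(m.specificity):>8}")
    return "\n".join(lines)


def parse_report(text: str) -> dict:
    """Inverse of :func:`format_report` (to the printed precision)."""
    lines = text.strip().splitlines()
    overall = float(lines[0].split(":")[1].strip().rstrip("%")) / 100.0
    per_class = {}
    for line in lines[2:]:
        k, sens, spec = line.split()
        per_class[int(k)] = ClassMetrics(
            accuracy=None,
            sensitivity=None if sens == "n/a" else float(sens) / 100.0,
            specificity=None if spec == "n/a" else float(spec) / 100.0,
        )
    return {"overall_accuracy": overall, "per_class": per_class}


def report_frame(report: dict) -> pd.DataFrame:
    """Delimited-text-friendly view of a multiclass report."""
    rows = [
        {
            "class": k,
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "accuracy": m.accuracy,
        }
        for k, m in report["per_class"].items()
    ]
    return pd.DataFrame(rows)
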