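"""Confusion-count segmentation metrics: IoU, Dice, recall, specificity,
precision, all reported as percentages."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict

import numpy as np

from .errors import InvalidInputError
from .nn import Tensor

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts",
           "evaluate_metrics", "aggregate_reports", "write_reports"]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass
class MetricsReport:
    iou: float
    dice: float
    recall: float
    specificity: float
    precision: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def _ratio(num: int, den: int) -> float:
    """Percentage num/den; an absent class (den == 0) scores 100 by
    convention — nothing to detect, nothing missed."""
    return 100.0 if den == 0 else 100.0 * num / den


def confusion_counts(pred, target, threshold: float = 0.5) -> ConfusionCounts:
    p = pred.data if isinstance(pred, Tensor) else np.asarray(pred, dtype=float)
    t = target.data if isinstance(target, Tensor) else np.asarray(target)
    if p.shape != t.shape:
        raise InvalidInputError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    tvals = np.unique(t)
    if not np.all(np.isin(tvals, (0, 1))):
        raise InvalidInputError(f"target is not binary; values {tvals[:5]}")
    if not 0.0 < threshold < 1.0:
        raise InvalidInputError("threshold must lie in (0, 1)")
    pb = p >= threshold
    tb = t.astype(bool)
    tp = int(np.count_nonzero(pb & tb))
    tn = int(np.count_nonzero(~pb & ~tb))
    fp = int(np.count_nonzero(pb & ~tb))
    fn = int(np.count_nonzero(~pb & tb))
    return ConfusionCounts(tp, tn, fp, fn)


def metrics_from_counts(c: ConfusionCounts) -> MetricsReport:
    return MetricsReport(
        iou=_ratio(c.tp, c.fp + c.tp + c.fn),
        dice=_ratio(2 * c.tp, c.fp + 2 * c.tp + c.fn),
        recall=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        precision=_ratio(c.tp, c.fp + c.tp),
    )


def evaluate_metrics(pred, target, threshold: float = 0.5) -> MetricsReport:
    """Binarize ``pred`` at ``threshold`` and derive the five percentages
    from the confusion counts."""
    return metrics_from_counts(confusion_counts(pred, target, threshold))


def aggregate_reports(reports: list[MetricsReport],
                      counts: list[ConfusionCounts] | None = None,
                      mode: str = "per_image") -> MetricsReport:
    """Aggregate per-image reports: ``per_image`` averages the percentages,
    ``pooled`` recomputes them from summed confusion counts."""
    if mode == "per_image":
        arr = np.array([[r.iou, r.dice, r.recall, r.specificity, r.precision]
                        for r in reports])
        return MetricsReport(*arr.mean(axis=0))
    if mode == "pooled":
        if counts is None:
            raise InvalidInputError("pooled aggregation needs confusion counts")
        total = counts[0]
        for c in counts[1:]:
            total = total + c
        return metrics_from_counts(total)
    raise InvalidInputError(f"unknown aggregation mode {mode!r}")


def write_reports(path_prefix, names: list[str], reports: list[MetricsReport],
                  aggregate: MetricsReport):
    """Serialize per-image rows plus an aggregate row to JSON and CSV."""
    rows = [{"image": n, **r.to_dict()} for n, r in zip(names, reports)]
    rows.append({"image": "aggregate", **aggregate.to_dict()})
    json_path = f"{path_prefix}.json"
    csv_path = f"{path_prefix}.csv"
    with open(json_path, "w") as fh:
        json.dump(rows, fh, indent=2)
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return json_path, csv_path
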