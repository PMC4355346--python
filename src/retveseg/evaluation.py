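"""Pixel-wise evaluation against manual ground truth.

Vessel pixels are the positive class.  Counts are tallied over the field
of view by default (the dark surround is trivially "correct" and would
inflate specificity and accuracy).  Metrics:

    Se  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    Acc = (TP + TN) / (TP + FN + TN + FP)

A zero denominator yields NaN plus an entry in ``MetricReport.undefined``
rather than a crash.  Dataset averages are unweighted per-image (macro)
means.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyEvaluationError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred: np.ndarray, truth: np.ndarray, fov: np.ndarray | None = None) -> ConfusionCounts:
    """Tally TP/FP/TN/FN over the FOV (or the full frame when fov is None)."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"prediction shape {pred.shape} does not match truth shape {truth.shape}")
    if fov is not None:
        fov = np.asarray(fov, dtype=bool)
        if fov.shape != pred.shape:
            raise ValueError(f"FOV shape {fov.shape} does not match prediction shape {pred.shape}")
        pred, truth = pred[fov], truth[fov]
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & truth)),
        fp=int(np.count_nonzero(pred & ~truth)),
        tn=int(np.count_nonzero(~pred & ~truth)),
        fn=int(np.count_nonzero(~pred & truth)),
    )


@dataclass
class MetricReport:
    sensitivity: float
    specificity: float
    accuracy: float
    counts: ConfusionCounts
    image_id: str | None = None
    undefined: frozenset = field(default_factory=frozenset)


def metrics(c: ConfusionCounts, image_id: str | None = None) -> MetricReport:
    """Compute Se/Sp/Acc from confusion counts."""
    if c.total == 0:
        raise EmptyEvaluationError("all confusion counts are zero; nothing was evaluated")
    undefined = set()

    def ratio(num, den, name):
        if den == 0:
            undefined.add(name)
            return math.nan
        return num / den

    se = ratio(c.tp, c.tp + c.fn, "sensitivity")
    sp = ratio(c.tn, c.tn + c.fp, "specificity")
    acc = (c.tp + c.tn) / c.total
    return MetricReport(sensitivity=se, specificity=sp, accuracy=acc,
                        counts=c, image_id=image_id, undefined=frozenset(undefined))


@dataclass
class DatasetReport:
    """Per-image reports plus their unweighted means."""

    cases: list
    mean_sensitivity: float
    mean_specificity: float
    mean_accuracy: float

    def rows(self) -> list[dict]:
        out = []
        for r in self.cases:
            out.append({
                "id": r.image_id, "Se": r.sensitivity, "Sp": r.specificity,
                "Acc": r.accuracy, "TP": r.counts.tp, "FP": r.counts.fp,
                "TN": r.counts.tn, "FN": r.counts.fn,
            })
        out.append({
            "id": "Average", "Se": self.mean_sensitivity, "Sp": self.mean_specificity,
            "Acc": self.mean_accuracy, "TP": "", "FP": "", "TN": "", "FN": "",
        })
        return out

    def to_csv(self, path) -> None:
        rows = self.rows()
        with open(Path(path), "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)

    def to_json(self, path) -> None:
        with open(Path(path), "w") as fh:
            json.dump(self.rows(), fh, indent=2)


def dataset_report(cases) -> DatasetReport:
    """Average per-image metrics (macro averaging; NaN metrics are skipped)."""
    cases = list(cases)
    if not cases:
        raise EmptyEvaluationError("no cases to report")
    with np.errstate(all="ignore"):
        mean_se = float(np.nanmean([c.sensitivity for c in cases]))
        mean_sp = float(np.nanmean([c.specificity for c in cases]))
        mean_acc = float(np.nanmean([c.accuracy for c in cases]))
    return DatasetReport(cases=cases, mean_sensitivity=mean_se,
                         mean_specificity=mean_sp, mean_accuracy=mean_acc)
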