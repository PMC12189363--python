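"""Segmentation metrics on hardened (argmax) predictions.

Everything is computed from per-class confusion counts:

    IoU_c       = TP / (TP + FP + FN)
    Precision_c = TP / (TP + FP)
    Recall_c    = TP / (TP + FN)
    Dice_c      = 2 P R / (P + R)   (identical to F1 on pixel sets)

Means are unweighted averages over the three classes, background included.
Batch-level records are aggregated across batches as mean +/- sample
standard deviation (n-1 denominator), which is how evaluation results are
reported.

Degenerate denominators follow an explicit convention: a class absent from
both masks scores 1.0 on every metric for that batch (perfect agreement on
absence; the alternative of skipping the class from the mean is available
via ``absent_policy="skip"``); a class present on one side only scores 0
where its ratio is 0/0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, StructuralError

METRIC_NAMES = ("iou", "precision", "recall", "dice", "f1")


@dataclass
class ConfusionCounts:
    """Per-class TP/FP/FN (and TN) pixel counts."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)


def confusion_counts(pred: np.ndarray, gt: np.ndarray,
                     n_classes: int = 3) -> ConfusionCounts:
    """Confusion counts of a predicted vs ground-truth label mask."""
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise StructuralError(f"pred {pred.shape} and gt {gt.shape} "
                              "disagree in shape")
    idx = gt.astype(np.int64).ravel() * n_classes + pred.astype(np.int64).ravel()
    cm = np.bincount(idx, minlength=n_classes * n_classes)
    cm = cm.reshape(n_classes, n_classes)          # rows gt, cols pred
    tp = np.diag(cm).astype(np.int64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = cm.sum() - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


@dataclass
class MetricsRecord:
    """Per-class and mean metrics of one batch (or one aggregate).

    ``per_class`` maps metric name -> array of length C; ``means`` maps
    metric name -> scalar; ``sds`` is populated by `aggregate_batches`.
    """

    per_class: dict[str, np.ndarray]
    means: dict[str, float]
    sds: dict[str, float] = field(default_factory=dict)
    n_batches: int = 1

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for name in METRIC_NAMES:
            row = {f"class_{c}": v for c, v in
                   enumerate(self.per_class[name])}
            row["mean"] = self.means[name]
            if self.sds:
                row["sd"] = self.sds[name]
            rows[name] = row
        return pd.DataFrame(rows).T

    def __getitem__(self, key: str) -> float:
        return self.means[key]


def _safe_ratio(num: np.ndarray, den: np.ndarray,
                degenerate: np.ndarray, fill: float) -> np.ndarray:
    out = np.zeros(len(num), dtype=np.float64)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    out[degenerate] = fill
    return out


def metrics_from_counts(cc: ConfusionCounts,
                        absent_policy: str = "one") -> MetricsRecord:
    """IoU / precision / recall / Dice / F1 from confusion counts.

    ``absent_policy`` controls classes absent from both masks: ``"one"``
    scores them 1.0 (default); ``"skip"`` excludes them from the means.
    """
    if absent_policy not in ("one", "skip"):
        raise ConfigError("absent_policy must be 'one' or 'skip'")
    tp = cc.tp.astype(np.float64)
    fp = cc.fp.astype(np.float64)
    fn = cc.fn.astype(np.float64)
    absent = (tp + fp + fn) == 0
    iou = _safe_ratio(tp, tp + fp + fn, absent, 1.0)
    precision = _safe_ratio(tp, tp + fp, absent, 1.0)
    recall = _safe_ratio(tp, tp + fn, absent, 1.0)
    dice = _safe_ratio(2.0 * precision * recall, precision + recall,
                       absent, 1.0)
    per_class = {"iou": iou, "precision": precision, "recall": recall,
                 "dice": dice, "f1": dice.copy()}
    if absent_policy == "skip" and absent.any() and not absent.all():
        keep = ~absent
        means = {k: float(v[keep].mean()) for k, v in per_class.items()}
    else:
        means = {k: float(v.mean()) for k, v in per_class.items()}
    means["f1"] = means["dice"]
    return MetricsRecord(per_class, means)


def aggregate_batches(records: list[MetricsRecord]) -> MetricsRecord:
    """Across-batch mean and sample SD of every metric (macro over batches)."""
    if not records:
        raise ConfigError("cannot aggregate an empty list of records")
    per_class = {}
    means, sds = {}, {}
    for name in METRIC_NAMES:
        stack = np.stack([r.per_class[name] for r in records])
        per_class[name] = stack.mean(axis=0)
        vals = np.array([r.means[name] for r in records], dtype=np.float64)
        means[name] = float(vals.mean())
        sds[name] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    means["f1"] = means["dice"]
    sds["f1"] = sds["dice"]
    return MetricsRecord(per_class, means, sds, n_batches=len(records))


def pooled_counts(counts: list[ConfusionCounts]) -> ConfusionCounts:
    """Micro-averaging substrate: confusion counts summed over batches."""
    if not counts:
        raise ConfigError("cannot pool an empty list of counts")
    return ConfusionCounts(
        tp=np.sum([c.tp for c in counts], axis=0),
        fp=np.sum([c.fp for c in counts], axis=0),
        fn=np.sum([c.fn for c in counts], axis=0),
        tn=np.sum([c.tn for c in counts], axis=0))
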