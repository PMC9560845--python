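"""Pixelwise segmentation metrics.

Everything reduces to the four confusion counts of a binary mask pair:
TP, FP, TN, FN. From those:

    DC   = 2*TP / (2*TP + FP + FN)          (Dice coefficient)
    IR   = IoUp = TP / (TP + FP + FN)       (intersection ratio / Jaccard)
    Rec  = Se = TP / (TP + FN)
    Spec = TN / (TN + FP)
    Prec = TP / (TP + FP)
    IoUb = TN / (TN + FP + FN)              (background IoU)
    mIoU = (IoUp + IoUb) / 2
    Ac   = (TP + TN) / total

plus AUC over the un-thresholded probability map. Dice and Jaccard obey
DC = 2*IR/(1 + IR).

Degenerate empty-vs-empty comparisons (TP = FP = FN = 0) score 1.0 for the
foreground overlap metrics — both raters agree there is nothing to find —
and a warning is logged.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "dice",
    "iou_poly",
    "iou_bg",
    "metric_report",
    "auc_score",
    "aggregate_reports",
    "write_reports",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of a binary prediction against a binary truth."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """All metric fields; ``se`` aliases ``rec`` and ``ir`` aliases ``ioup``."""

    dc: float
    ir: float
    rec: float
    spec: float
    prec: float
    ioup: float
    ioub: float
    miou: float
    ac: float
    se: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _as_binary(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr)
    uniq = np.unique(a)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError(f"{name} must be strictly binary; found values {uniq[:10]}")
    return a.astype(bool)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally TP/FP/TN/FN between two same-shaped strictly binary masks."""
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int, degenerate: float = 1.0, what: str = "metric") -> float:
    if den == 0:
        warnings.warn(
            f"{what} is degenerate (empty-vs-empty); scoring {degenerate} by convention",
            stacklevel=3,
        )
        return degenerate
    return num / den


def dice(c: ConfusionCounts) -> float:
    """Dice coefficient 2*TP / (2*TP + FP + FN)."""
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, what="Dice")


def iou_poly(c: ConfusionCounts) -> float:
    """Foreground IoU (the intersection ratio IR): TP / (TP + FP + FN)."""
    return _ratio(c.tp, c.tp + c.fp + c.fn, what="IoU")


def iou_bg(c: ConfusionCounts) -> float:
    """Background IoU: TN / (TN + FP + FN)."""
    return _ratio(c.tn, c.tn + c.fp + c.fn, what="background IoU")


def auc_score(prob: np.ndarray, truth: np.ndarray) -> float:
    """Area under the ROC curve of pixel probabilities against truth."""
    t = _as_binary(truth, "truth").ravel()
    p = np.asarray(prob, dtype=float).ravel()
    if p.shape != t.shape:
        raise ValueError("prob and truth must have the same number of pixels")
    if t.all() or not t.any():
        raise ValueError("AUC is undefined: truth contains a single class")
    return float(roc_auc_score(t, p))


def metric_report(
    prob: np.ndarray, truth: np.ndarray, threshold: float = 0.5
) -> MetricReport:
    """Binarize ``prob`` at ``threshold`` and fill every metric field.

    AUC uses the un-thresholded probabilities and is NaN when the truth is
    single-class (where the ROC is undefined).
    """
    p = np.asarray(prob, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("prob values must lie in [0, 1]")
    c = confusion_counts((p >= threshold).astype(np.uint8), truth)
    ioup = iou_poly(c)
    ioub = iou_bg(c)
    rec = _ratio(c.tp, c.tp + c.fn, what="recall")
    try:
        auc = auc_score(p, truth)
    except ValueError:
        auc = float("nan")
    return MetricReport(
        dc=dice(c),
        ir=ioup,
        rec=rec,
        spec=_ratio(c.tn, c.tn + c.fp, what="specificity"),
        prec=_ratio(c.tp, c.tp + c.fp, what="precision"),
        ioup=ioup,
        ioub=ioub,
        miou=(ioup + ioub) / 2.0,
        ac=(c.tp + c.tn) / c.total,
        se=rec,
        auc=auc,
    )


def aggregate_reports(
    reports: Sequence[MetricReport], mode: str = "macro"
) -> dict[str, float]:
    """Average per-image reports. ``macro`` (default) is the unweighted mean
    of per-image values; NaN AUCs (single-class images) are skipped."""
    if mode != "macro":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if not reports:
        raise ValueError("no reports to aggregate")
    out: dict[str, float] = {}
    for k in MetricReport.__dataclass_fields__:
        vals = np.array([getattr(r, k) for r in reports], dtype=float)
        out[k] = float(np.nanmean(vals)) if np.isnan(vals).any() else float(vals.mean())
    return out


def micro_report(
    probs: Iterable[np.ndarray], truths: Iterable[np.ndarray], threshold: float = 0.5
) -> MetricReport:
    """Micro-average: pool all pixels before computing one report."""
    p = np.concatenate([np.asarray(x, dtype=float).ravel() for x in probs])
    t = np.concatenate([np.asarray(x).ravel() for x in truths])
    return metric_report(p, t, threshold=threshold)


def write_reports(
    per_image: dict[str, MetricReport],
    aggregate: dict[str, float],
    out_dir: str | Path,
    stem: str = "metrics",
) -> tuple[Path, Path]:
    """Emit per-image + aggregate metrics as CSV and JSON; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fields = list(MetricReport.__dataclass_fields__)
    csv_path = out_dir / f"{stem}.csv"
    with open(csv_path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["image"] + fields)
        for name, rep in per_image.items():
            w.writerow([name] + [f"{getattr(rep, k):.6f}" for k in fields])
        w.writerow(["__aggregate__"] + [f"{aggregate[k]:.6f}" for k in fields])
    json_path = out_dir / f"{stem}.json"
    payload = {
        "per_image": {n: r.as_dict() for n, r in per_image.items()},
        "aggregate": aggregate,
    }
    json_path.write_text(json.dumps(payload, indent=2))
    logger.info("wrote metric reports to %s and %s", csv_path, json_path)
    return csv_path, json_path
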