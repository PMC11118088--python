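"""Confusion-matrix tallies and segmentation metrics.

ACC = (TP + TN) / (TP + TN + FP + FN)
SE  = TP / (TP + FN)            (sensitivity / recall on the vessel class)
SP  = TN / (TN + FP)            (specificity on the background)
F1  = 2 TP / (2 TP + FN + FP)

Counts may be restricted to a field-of-view mask.  Zero denominators report
the affected metric as 0 with a warning.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .errors import DimensionError


@dataclass(frozen=True)
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


@dataclass(frozen=True)
class Metrics:
    acc: float
    se: float
    sp: float
    f1: float


def confusion_counts(pred: np.ndarray, gt: np.ndarray,
                     fov: np.ndarray | None = None) -> ConfusionCounts:
    """Tally TP/TN/FP/FN over the FOV (or everywhere if no FOV given)."""
    pred = np.asarray(pred) > 0
    gt = np.asarray(gt) > 0
    if pred.shape != gt.shape:
        raise DimensionError(f"prediction {pred.shape} does not match ground truth {gt.shape}")
    if fov is not None:
        fov = np.asarray(fov) > 0
        if fov.shape != gt.shape:
            raise DimensionError(f"FOV {fov.shape} does not match ground truth {gt.shape}")
        pred, gt = pred[fov], gt[fov]
    tp = int(np.count_nonzero(pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    return ConfusionCounts(tp, tn, fp, fn)


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} denominator is zero; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> Metrics:
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    return Metrics(
        acc=(c.tp + c.tn) / c.total,
        se=_safe_div(c.tp, c.tp + c.fn, "sensitivity"),
        sp=_safe_div(c.tn, c.tn + c.fp, "specificity"),
        f1=_safe_div(2 * c.tp, 2 * c.tp + c.fn + c.fp, "F1"),
    )


def back_resize_prediction(pred: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resize of a binary prediction to a native resolution,
    for scoring against the unresized ground truth."""
    from .data_pipeline import resize_mask

    if pred.shape == tuple(shape):
        return pred
    if shape[0] != shape[1]:
        from skimage import transform

        out = transform.resize(pred.astype(np.uint8), shape, order=0,
                               preserve_range=True, anti_aliasing=False)
        return (out > 0.5).astype(np.uint8)
    return resize_mask(pred.astype(np.uint8), shape[0])


def evaluate_pairs(pairs, fovs=None) -> tuple[list[Metrics], Metrics]:
    """Per-image metrics plus pooled-count aggregate metrics.

    pairs: iterable of (pred, gt) binary masks; fovs: optional parallel
    iterable of FOV masks (entries may be None).
    """
    per_image = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    fov_list = list(fovs) if fovs is not None else None
    for i, (pred, gt) in enumerate(pairs):
        fov = fov_list[i] if fov_list is not None else None
        c = confusion_counts(pred, gt, fov)
        per_image.append(compute_metrics(c))
        pooled = pooled + c
    return per_image, compute_metrics(pooled)


def write_metrics(out_dir, stems: list[str], per_image: list[Metrics],
                  aggregate: Metrics) -> tuple[Path, Path]:
    """Emit `metrics.csv` (stem,ACC,SE,SP,F1 rows) and `metrics.json`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "metrics.csv"
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["stem", "ACC", "SE", "SP", "F1"])
        for stem, m in zip(stems, per_image):
            w.writerow([stem, f"{m.acc:.6f}", f"{m.se:.6f}", f"{m.sp:.6f}", f"{m.f1:.6f}"])
        w.writerow(["aggregate", f"{aggregate.acc:.6f}", f"{aggregate.se:.6f}",
                    f"{aggregate.sp:.6f}", f"{aggregate.f1:.6f}"])
    json_path = out_dir / "metrics.json"
    with open(json_path, "w") as fh:
        json.dump({"per_image": {s: asdict(m) for s, m in zip(stems, per_image)},
                   "aggregate": asdict(aggregate)}, fh, indent=2)
    return csv_path, json_path
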