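"""Pixel-level evaluation against gold-standard vessel masks.

Confusion counts (TP/FP/TN/FN) restricted to the field of view, the
three standard metrics

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + FP + TN + FN)

a disagreement overlay (TP green, FP blue, FN red over a grayscale
background), and a side-by-side report against two gold standards, as
used with the STARE dataset whose second observer marks many more small
vessels than the first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["ConfusionCounts", "Metrics", "confusion", "metrics", "overlay",
           "dual_gold_report", "jaccard"]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float


def _check_shapes(*arrays) -> None:
    shapes = {np.asarray(a).shape for a in arrays if a is not None}
    if len(shapes) > 1:
        raise ValueError(f"mask shapes differ: {sorted(shapes)}")


def confusion(
    pred: np.ndarray, gold: np.ndarray, fov: np.ndarray | None = None
) -> ConfusionCounts:
    """Count TP/FP/TN/FN pixels, restricted to the FOV when given."""
    pred = np.asarray(pred, dtype=bool)
    gold = np.asarray(gold, dtype=bool)
    _check_shapes(pred, gold, fov)
    if fov is not None:
        sel = np.asarray(fov, dtype=bool)
        pred, gold = pred[sel], gold[sel]
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & gold)),
        fp=int(np.count_nonzero(pred & ~gold)),
        tn=int(np.count_nonzero(~pred & ~gold)),
        fn=int(np.count_nonzero(~pred & gold)),
    )


def metrics(c: ConfusionCounts, accuracy_as_printed: bool = False) -> Metrics:
    """Accuracy, sensitivity and specificity from confusion counts.

    A metric whose denominator is zero is reported as NaN with a
    warning. ``accuracy_as_printed`` reproduces the TN-only accuracy
    numerator variant for literal comparison; the standard
    (TP+TN)/total is the default.
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero")

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
            return float("nan")
        return num / den

    acc_num = c.tn if accuracy_as_printed else c.tp + c.tn
    return Metrics(
        accuracy=acc_num / c.total,
        sensitivity=_ratio(c.tp, c.tp + c.fn, "sensitivity"),
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity"),
    )


def jaccard(pred: np.ndarray, gold: np.ndarray, fov: np.ndarray | None = None) -> float:
    """Intersection-over-union of the two vessel masks (in-FOV)."""
    pred = np.asarray(pred, dtype=bool)
    gold = np.asarray(gold, dtype=bool)
    _check_shapes(pred, gold, fov)
    if fov is not None:
        sel = np.asarray(fov, dtype=bool)
        pred, gold = pred[sel], gold[sel]
    union = np.count_nonzero(pred | gold)
    if union == 0:
        return 1.0
    return np.count_nonzero(pred & gold) / union


def overlay(
    pred: np.ndarray,
    gold: np.ndarray,
    fov: np.ndarray | None = None,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Disagreement overlay: TP green, FP blue, FN red, TN grayscale.

    Returns an (H, W, 3) uint8 raster; ``background`` optionally
    supplies the grayscale base (a [0, 1] image), otherwise black.
    """
    pred = np.asarray(pred, dtype=bool)
    gold = np.asarray(gold, dtype=bool)
    _check_shapes(pred, gold, fov, background)
    if fov is not None:
        sel = np.asarray(fov, dtype=bool)
        pred = pred & sel
        gold = gold & sel
    if background is None:
        base = np.zeros(pred.shape, dtype=np.uint8)
    else:
        base = (np.clip(np.asarray(background, float), 0, 1) * 255).astype(np.uint8)
    img = np.stack([base] * 3, axis=-1)
    img[pred & gold] = (0, 255, 0)
    img[pred & ~gold] = (0, 0, 255)
    img[~pred & gold] = (255, 0, 0)
    return img


def _metric_row(name: str, pred, gold, fov) -> dict:
    c = confusion(pred, gold, fov)
    m = metrics(c)
    row = {"gold": name, **asdict(c), **asdict(m)}
    return row


def dual_gold_report(
    pred: np.ndarray,
    gold1: np.ndarray,
    gold2: np.ndarray | None = None,
    fov: np.ndarray | None = None,
    width_map: np.ndarray | None = None,
    small_width: float = 2.0,
) -> list[dict]:
    """Metrics against one or two gold standards, as table rows.

    When a per-pixel true width map is available (phantom runs), extra
    rows score sensitivity on small vessels only (width <= small_width
    pixels), the regime where observers and methods disagree most.
    """
    rows = [_metric_row("gold1", pred, gold1, fov)]
    if gold2 is not None:
        rows.append(_metric_row("gold2", pred, gold2, fov))
    if width_map is not None:
        width_map = np.asarray(width_map, dtype=float)
        for name, gold in (("gold1", gold1), ("gold2", gold2)):
            if gold is None:
                continue
            small = np.asarray(gold, bool) & (width_map > 0) & (width_map <= small_width)
            n_small = int(np.count_nonzero(small if fov is None else small & fov))
            if n_small == 0:
                continue
            c = confusion(pred, small, fov)
            # only sensitivity is meaningful on the small-vessel subset
            rows.append(
                {
                    "gold": f"{name}_small_vessels",
                    "tp": c.tp, "fp": None, "tn": None, "fn": c.fn,
                    "accuracy": None,
                    "sensitivity": c.tp / (c.tp + c.fn),
                    "specificity": None,
                }
            )
    return rows
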