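"""Segmentation overlap metrics.

Per-label, one-vs-rest comparison of a predicted label map against a
reference: Sørensen-Dice index, Jaccard index (JI), conformity coefficient
(CC), true positive rate (TPR), true negative rate (TNR), positive
predictive value (PPV) and volume ratio (VR).

With the usual confusion counts (label treated as positive, everything
else negative):

    Dice = 2 TP / (2 TP + FP + FN)        JI = TP / (TP + FP + FN)
    CC   = (3 Dice - 2) / Dice            TPR = TP / (TP + FN)
    TNR  = TN / (TN + FP)                 PPV = TP / (TP + FP)
    VR   = predicted volume / reference volume

CC is negative whenever Dice < 2/3 and is undefined at Dice = 0.  The TNR
is computed over the full grid, so for a small structure in a large volume
it sits near 1.  An undefined denominator yields ``nan`` rather than an
arbitrary convention value; aggregate rows skip ``nan`` entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dixon import SegmentationMask
from .labels import MuscleLabelScheme

__all__ = [
    "ConfusionCounts",
    "OverlapMetrics",
    "confusion_counts",
    "overlap_metrics",
    "metrics_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class OverlapMetrics:
    dice: float
    ji: float
    cc: float
    tpr: float
    tnr: float
    ppv: float
    vr: float

    def as_dict(self) -> dict:
        return {
            "dice": self.dice,
            "ji": self.ji,
            "cc": self.cc,
            "tpr": self.tpr,
            "tnr": self.tnr,
            "ppv": self.ppv,
            "vr": self.vr,
        }


def _grids(gt, pred):
    g = gt.labels if isinstance(gt, SegmentationMask) else np.asarray(gt)
    p = pred.labels if isinstance(pred, SegmentationMask) else np.asarray(pred)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: gt {g.shape} vs pred {p.shape}")
    return g, p


def confusion_counts(gt, pred, label: int) -> ConfusionCounts:
    """TP/FP/FN/TN over all grid voxels with ``label`` treated as positive."""
    g, p = _grids(gt, pred)
    gpos = g == label
    ppos = p == label
    tp = int(np.count_nonzero(gpos & ppos))
    fp = int(np.count_nonzero(~gpos & ppos))
    fn = int(np.count_nonzero(gpos & ~ppos))
    tn = g.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics_from_counts(c: ConfusionCounts) -> OverlapMetrics:
    """The seven metrics from confusion counts; nan where undefined."""

    def ratio(num, den):
        return num / den if den > 0 else math.nan

    dice = ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    ji = ratio(c.tp, c.tp + c.fp + c.fn)
    cc = (3.0 * dice - 2.0) / dice if dice and dice > 0 else math.nan
    tpr = ratio(c.tp, c.tp + c.fn)
    tnr = ratio(c.tn, c.tn + c.fp)
    ppv = ratio(c.tp, c.tp + c.fp)
    vr = ratio(c.tp + c.fp, c.tp + c.fn)  # predicted volume / reference volume
    return OverlapMetrics(dice=dice, ji=ji, cc=cc, tpr=tpr, tnr=tnr, ppv=ppv, vr=vr)


def overlap_metrics(gt, pred, label: int) -> OverlapMetrics:
    """All seven metrics for one label between reference and prediction."""
    return metrics_from_counts(confusion_counts(gt, pred, label))


def metrics_report(
    gt,
    pred,
    scheme: MuscleLabelScheme,
    scan_id: str | None = None,
) -> pd.DataFrame:
    """Per-muscle metric table, one row per scheme label plus a mean row.

    The aggregate row reports mean and standard error across labels,
    skipping undefined entries.
    """
    rows = []
    for group in scheme:
        for side, label in (("left", group.left_label), ("right", group.right_label)):
            m = overlap_metrics(gt, pred, label)
            row = {"label": label, "group": group.name, "side": side}
            row.update(m.as_dict())
            rows.append(row)
    df = pd.DataFrame(rows)
    metric_cols = ["dice", "ji", "cc", "tpr", "tnr", "ppv", "vr"]
    mean_row = {"label": -1, "group": "mean", "side": ""}
    se_row = {"label": -1, "group": "se", "side": ""}
    for col in metric_cols:
        vals = df[col].dropna()
        mean_row[col] = float(vals.mean()) if len(vals) else math.nan
        se_row[col] = (
            float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else math.nan
        )
    df = pd.concat([df, pd.DataFrame([mean_row, se_row])], ignore_index=True)
    if scan_id is not None:
        df.insert(0, "scan_id", scan_id)
    return df
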