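"""Reference segmentation losses and evaluation metrics.

Framework-free forward-value implementations of the per-pixel multi-label
binary cross-entropy used for overlapping tooth-position recognition, the
softmax cross-entropy used for single-label region segmentation, and the
five pixel metrics (F1/Dice, IoU, pixel accuracy, sensitivity, specificity)
plus precision.  Metrics with a zero denominator return ``None`` — an
explicit "undefined" marker — rather than propagating NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import log_softmax

from .masks import RegionMap, ToothPositionStack
from .measurement import Stage

logger = logging.getLogger(__name__)

#: probability clamp for the losses; avoids -inf without moving values at 4 d.p.
PROB_EPS = 1e-7


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise MetricError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise TP/FP/FN/TN between two binary grids of equal shape."""
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise MetricError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    return ConfusionCounts(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
        tn=int((~p & ~t).sum()),
    )


def f1_score(c: ConfusionCounts) -> Optional[float]:
    """Dice / F1 = 2TP / (2TP + FP + FN); None when undefined."""
    den = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / den if den else None


def iou(c: ConfusionCounts) -> Optional[float]:
    """Intersection over union = TP / (TP + FN + FP); None when undefined."""
    den = c.tp + c.fn + c.fp
    return c.tp / den if den else None


def pixel_accuracy(c: ConfusionCounts) -> Optional[float]:
    den = c.total
    return (c.tp + c.tn) / den if den else None


def sensitivity(c: ConfusionCounts) -> Optional[float]:
    """Recall = TP / (TP + FN); None when there are no positives."""
    den = c.tp + c.fn
    return c.tp / den if den else None


def specificity(c: ConfusionCounts) -> Optional[float]:
    den = c.tn + c.fp
    return c.tn / den if den else None


def precision(c: ConfusionCounts) -> Optional[float]:
    den = c.tp + c.fp
    return c.tp / den if den else None


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R) of a precision/recall pair."""
    if precision < 0 or recall < 0:
        raise MetricError("precision and recall must be non-negative")
    if precision + recall == 0:
        raise MetricError("harmonic mean undefined: precision and recall both zero")
    return 2 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# losses

def multilabel_loss(pred: np.ndarray, labels: np.ndarray, eps: float = PROB_EPS) -> float:
    """Mean per-pixel, per-class binary cross-entropy for multi-label masks.

    ``pred`` holds sigmoid probabilities in [0, 1] of shape (H, W, C);
    ``labels`` binary indicators of the same shape.  Each of the H*W*C terms
    is -[y log p + (1-y) log(1-p)] with p clamped to [eps, 1-eps].  A pixel
    may belong to several classes; the channels are scored independently.
    """
    p = np.asarray(pred, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise MetricError(f"shape mismatch: pred {p.shape} vs labels {y.shape}")
    if p.min() < 0 or p.max() > 1:
        raise MetricError("pred probabilities must lie in [0, 1]")
    p = np.clip(p, eps, 1 - eps)
    terms = y * np.log(p) + (1 - y) * np.log1p(-p)
    return float(-terms.mean())


def cross_entropy_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean softmax cross-entropy over pixels for single-label masks.

    ``logits`` has shape (H, W, C); ``labels`` is one-hot over the channel
    axis with exactly one class per pixel.  Softmax normalizes the
    exponentiated logits across classes per pixel; the loss is the mean over
    pixels of the negative log-probability of the true class.
    """
    z = np.asarray(logits, dtype=float)
    y = np.asarray(labels)
    if z.shape != y.shape:
        raise MetricError(f"shape mismatch: logits {z.shape} vs labels {y.shape}")
    counts = y.sum(axis=-1)
    if not (counts == 1).all():
        raise MetricError("labels must be one-hot: exactly one class per pixel")
    logp = log_softmax(z, axis=-1)
    return float(-(logp * y).sum(axis=-1).mean())


# ---------------------------------------------------------------------------
# report builders

GridInput = Union[RegionMap, ToothPositionStack]


def _class_masks(item: GridInput) -> Dict[object, np.ndarray]:
    if isinstance(item, RegionMap):
        # Table-style per-class rows cover the foreground classes only
        return {lbl: item.region(lbl) for lbl in (1, 2, 3)}
    if isinstance(item, ToothPositionStack):
        return dict(item.masks)
    raise MetricError(f"unsupported input type {type(item).__name__}")


CLASS_NAMES = {1: "intrabony", 2: "suprabony", 3: "crown"}


def segmentation_report(
    preds: Sequence[GridInput], truths: Sequence[GridInput]
) -> pd.DataFrame:
    """Per-class and overall IoU/F1 over aligned prediction/truth pairs.

    Counts are pooled per class across images (micro within class), then
    per-class metrics are computed; the ``macro`` row is the unweighted mean
    over classes with defined metrics and the ``pooled`` row pools every
    class's counts together.  Classes absent from both prediction and truth
    everywhere are reported as undefined (NaN) and excluded from the macro
    with a logged note.
    """
    if len(preds) == 0 or len(preds) != len(truths):
        raise MetricError("need equal, non-empty prediction and truth lists")
    pooled: Dict[object, ConfusionCounts] = {}
    for pr, tr in zip(preds, truths):
        pm, tm = _class_masks(pr), _class_masks(tr)
        for cls in sorted(set(pm) | set(tm), key=str):
            shape = next(iter(pm.values())).shape if pm else next(iter(tm.values())).shape
            p = pm.get(cls, np.zeros(shape, dtype=bool))
            t = tm.get(cls, np.zeros(shape, dtype=bool))
            c = confusion_counts(p, t)
            prev = pooled.get(cls)
            pooled[cls] = ConfusionCounts(
                tp=c.tp + (prev.tp if prev else 0),
                fp=c.fp + (prev.fp if prev else 0),
                fn=c.fn + (prev.fn if prev else 0),
                tn=c.tn + (prev.tn if prev else 0),
            )
    rows = []
    per_class_vals = []
    for cls in sorted(pooled, key=str):
        c = pooled[cls]
        vals = {"iou": iou(c), "f1": f1_score(c)}
        if vals["iou"] is None:
            logger.warning("class %r absent everywhere; excluded from macro", cls)
        else:
            per_class_vals.append(vals)
        rows.append({"class": CLASS_NAMES.get(cls, cls), **{k: (np.nan if v is None else v) for k, v in vals.items()}})
    if per_class_vals:
        rows.append(
            {
                "class": "macro",
                "iou": float(np.mean([v["iou"] for v in per_class_vals])),
                "f1": float(np.mean([v["f1"] for v in per_class_vals])),
            }
        )
    allc = ConfusionCounts(
        tp=sum(c.tp for c in pooled.values()),
        fp=sum(c.fp for c in pooled.values()),
        fn=sum(c.fn for c in pooled.values()),
        tn=sum(c.tn for c in pooled.values()),
    )
    rows.append({"class": "pooled", "iou": iou(allc), "f1": f1_score(allc)})
    return pd.DataFrame(rows, columns=["class", "iou", "f1"]).set_index("class")


STAGE_REPORT_COLUMNS = ["precision", "sensitivity", "f1", "specificity", "support"]


def stage_report(
    pred_stages: Sequence[Stage],
    ref_stages: Sequence[Stage],
    method_label: str = "",
) -> pd.DataFrame:
    """One-vs-rest per-stage precision/sensitivity/F1/specificity table.

    ``support`` is the number of reference teeth per stage; the macro row is
    the unweighted mean over the three stages (undefined per-stage values
    are excluded with a warning).  Mirrors a per-stage staging evaluation
    table with a macro-average footer.
    """
    if len(pred_stages) != len(ref_stages):
        raise MetricError(
            f"length mismatch: {len(pred_stages)} predictions vs {len(ref_stages)} references"
        )
    if len(ref_stages) == 0:
        raise MetricError("empty stage lists")
    for s in list(pred_stages) + list(ref_stages):
        if not isinstance(s, Stage):
            raise MetricError(f"unknown stage value {s!r}")
    pred = np.asarray([s.value for s in pred_stages])
    ref = np.asarray([s.value for s in ref_stages])
    rows = []
    macro_acc: Dict[str, List[float]] = {k: [] for k in ("precision", "sensitivity", "f1", "specificity")}
    for stage in (Stage.I, Stage.II, Stage.III):
        c = confusion_counts(pred == stage.value, ref == stage.value)
        vals = {
            "precision": precision(c),
            "sensitivity": sensitivity(c),
            "f1": f1_score(c),
            "specificity": specificity(c),
        }
        for k, v in vals.items():
            if v is None:
                logger.warning("stage %s: %s undefined; excluded from macro", stage.name, k)
            else:
                macro_acc[k].append(v)
        label = f"Stage {stage.name}" + (f" ({method_label})" if method_label else "")
        rows.append({"row": label, **{k: (np.nan if v is None else v) for k, v in vals.items()},
                     "support": int(c.tp + c.fn)})
    macro_label = "Macro avg" + (f" ({method_label})" if method_label else "")
    rows.append(
        {
            "row": macro_label,
            **{k: float(np.mean(v)) if v else np.nan for k, v in macro_acc.items()},
            "support": len(ref),
        }
    )
    return pd.DataFrame(rows, columns=["row", *STAGE_REPORT_COLUMNS]).set_index("row")


def format_table(df: pd.DataFrame, floatfmt: str = "%.4f") -> str:
    """Aligned-text rendering of a report table."""
    return df.to_string(float_format=lambda x: floatfmt % x)
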