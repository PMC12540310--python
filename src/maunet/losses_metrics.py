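"""Compound BCE + Dice loss and nested-region evaluation metrics.

Training targets are the three nested binary regions used throughout
brain-tumor segmentation evaluation:

* whole tumor   WT = NCR ∪ ED ∪ ET
* tumor core    TC = NCR ∪ ET
* enhancing     ET

so a single multi-label sigmoid head covers all three, and the loss

    l = α · l_bce + β · l_dice          (defaults α = 1, β = 0.5)

averages binary cross-entropy and soft Dice over the three channels.
Evaluation reports Dice, sensitivity, specificity and precision from
exact voxel confusion counts per region.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor

# BraTS label convention
LBL_BACKGROUND, LBL_NCR, LBL_ED, LBL_ET = 0, 1, 2, 4
VALID_LABELS = frozenset({LBL_BACKGROUND, LBL_NCR, LBL_ED, LBL_ET})

REGIONS = ("wt", "tc", "et")

DICE_EPS = 1e-5
BCE_EPS = 1e-7


@dataclasses.dataclass
class RegionMaskSet:
    """Nested binary masks; invariant et ⊆ tc ⊆ wt."""

    wt: np.ndarray
    tc: np.ndarray
    et: np.ndarray

    def stack(self) -> np.ndarray:
        return np.stack([self.wt, self.tc, self.et]).astype(np.float64)

    def check_nesting(self) -> bool:
        return bool(np.all(self.et <= self.tc) and np.all(self.tc <= self.wt))


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclasses.dataclass
class LossWeights:
    alpha: float = 1.0   # BCE weight
    beta: float = 0.5    # Dice weight

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be nonnegative")


def encode_regions(labels: np.ndarray) -> RegionMaskSet:
    """Map an integer compartment volume to the nested region masks."""
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - VALID_LABELS
    if bad:
        raise ValueError(f"unknown label values {sorted(bad)}; expected {sorted(VALID_LABELS)}")
    ncr = labels == LBL_NCR
    ed = labels == LBL_ED
    et = labels == LBL_ET
    return RegionMaskSet(wt=ncr | ed | et, tc=ncr | et, et=et)


def decode_regions(region_masks: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_regions` for thresholded predictions.

    Nesting-aware: ET wins, then TC (⇒ NCR), then WT (⇒ ED).
    """
    wt, tc, et = (np.asarray(m).astype(bool) for m in region_masks)
    out = np.zeros(wt.shape, dtype=np.int16)
    out[wt] = LBL_ED
    out[tc] = LBL_NCR
    out[et] = LBL_ET
    return out


# -- losses ------------------------------------------------------------------

def bce_loss(pred, target) -> Tensor:
    """Mean binary cross-entropy; predictions are probabilities."""
    pred = nn.as_tensor(pred)
    target = nn.as_tensor(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = T.clamp(pred, BCE_EPS, 1.0 - BCE_EPS)
    return -(target * T.log(p) + (1.0 - target) * T.log(1.0 - p)).mean()


def dice_loss(pred, target, eps: float = DICE_EPS) -> Tensor:
    """Soft Dice loss 1 − (2|A∩B| + ε)/(|A| + |B| + ε)."""
    pred = nn.as_tensor(pred)
    target = nn.as_tensor(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    inter = (pred * target).sum()
    denom = pred.sum() + target.sum()
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def combined_loss(pred, target, w: LossWeights | None = None) -> Tensor:
    """α·BCE + β·Dice, each averaged over the three region channels.

    ``pred`` is the (3, D, H, W) probability field; ``target`` either a
    :class:`RegionMaskSet` or an equally shaped binary array.
    """
    w = w or LossWeights()
    if isinstance(target, RegionMaskSet):
        target = target.stack()
    pred = nn.as_tensor(pred)
    target = nn.as_tensor(np.asarray(target, dtype=float))
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    n_regions = pred.shape[0]
    bce = bce_loss(pred, target)
    dice_terms = [dice_loss(pred[i], target[i]) for i in range(n_regions)]
    dice = dice_terms[0]
    for t in dice_terms[1:]:
        dice = dice + t
    dice = dice * (1.0 / n_regions)
    return w.alpha * bce + w.beta * dice


# -- metrics -----------------------------------------------------------------

def confusion(pred_mask, target) -> ConfusionCounts:
    pred_mask = np.asarray(pred_mask)
    target = np.asarray(target)
    if pred_mask.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred_mask.shape} vs {target.shape}")
    for name, arr in (("prediction", pred_mask), ("target", target)):
        if not np.isin(arr, (0, 1, False, True)).all():
            raise ValueError(f"{name} mask is not binary")
    p = pred_mask.astype(bool)
    t = target.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & t)), tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)), fn=int(np.sum(~p & t)))


def _ratio(num: int, den: int, both_empty: bool) -> float:
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def metrics(c: ConfusionCounts, printed_specificity: bool = False) -> dict[str, float]:
    """Dice, sensitivity, specificity, precision from confusion counts.

    Empty-denominator convention: a ratio whose denominator vanishes is
    1.0 when both prediction and target are empty (nothing to find,
    nothing found), else 0.0.  ``printed_specificity`` switches to the
    nonstandard TN/(TP+FP) variant kept for compatibility.
    """
    both_empty = (c.tp + c.fp + c.fn) == 0
    spec_den = (c.tp + c.fp) if printed_specificity else (c.tn + c.fp)
    return {
        "dice": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, both_empty),
        "sensitivity": _ratio(c.tp, c.tp + c.fn, both_empty),
        "specificity": _ratio(c.tn, spec_den, c.tn == 0 and spec_den == 0),
        "precision": _ratio(c.tp, c.tp + c.fp, both_empty),
    }


def region_metrics(pred_regions: np.ndarray, target: RegionMaskSet) -> dict[str, dict[str, float]]:
    """Per-region metric dict for a thresholded (3, D, H, W) prediction."""
    target_stack = target.stack()
    return {region: metrics(confusion(pred_regions[i] > 0.5, target_stack[i] > 0.5))
            for i, region in enumerate(REGIONS)}


def metrics_table(per_case: dict[str, dict[str, dict[str, float]]]) -> pd.DataFrame:
    """Long-format table: one row per case × region.

    ``per_case`` maps case_id → region → metric → value, matching
    :func:`region_metrics` output.
    """
    rows = [{"case_id": cid, "region": region, **vals}
            for cid, regions in per_case.items()
            for region, vals in regions.items()]
    return pd.DataFrame(rows, columns=["case_id", "region", "dice", "sensitivity",
                                       "specificity", "precision"])
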