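"""Composite detection loss: complete-IoU box loss, binary cross-entropy
classification, and distribution focal regression.

The three components are combined with fixed weights

    total = 7.5 * box_loss + 0.5 * cls_loss + 1.5 * dfl_loss

and the box/regression terms are normalised by the clamped sum of the
assignment's soft target scores, max(sum target_scores, 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import tensor as T
from .assigner import TargetAssignment
from .tensor import Tensor

BOX_WEIGHT = 7.5
CLS_WEIGHT = 0.5
DFL_WEIGHT = 1.5


@dataclass
class LossBreakdown:
    box_loss: float
    cls_loss: float
    dfl_loss: float
    total: float
    target_scores_sum: float

    def weighted_identity_residual(self) -> float:
        return abs(self.total - (BOX_WEIGHT * self.box_loss +
                                 CLS_WEIGHT * self.cls_loss +
                                 DFL_WEIGHT * self.dfl_loss))


# ---------------------------------------------------------------------------
# Complete IoU
# ---------------------------------------------------------------------------

def ciou(a, b, eps: float = 1e-9) -> float:
    """Complete IoU of two boxes: IoU - rho^2/c^2 - alpha*v.

    rho is the centre distance, c the enclosing-box diagonal, and v the
    squared normalised aspect-ratio angle difference.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    for box in (a, b):
        if box[2] <= box[0] or box[3] <= box[1]:
            raise ValueError(f"degenerate box {box.tolist()}")
    iw = max(min(a[2], b[2]) - max(a[0], b[0]), 0.0)
    ih = max(min(a[3], b[3]) - max(a[1], b[1]), 0.0)
    inter = iw * ih
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    iou = inter / (area_a + area_b - inter + eps)
    cw = max(a[2], b[2]) - min(a[0], b[0])
    ch = max(a[3], b[3]) - min(a[1], b[1])
    c2 = cw * cw + ch * ch + eps
    rho2 = ((a[0] + a[2] - b[0] - b[2]) ** 2 + (a[1] + a[3] - b[1] - b[3]) ** 2) / 4
    v = (4 / math.pi ** 2) * (math.atan((b[2] - b[0]) / (b[3] - b[1]))
                              - math.atan((a[2] - a[0]) / (a[3] - a[1]))) ** 2
    alpha = v / (1 - iou + v + eps)
    return float(iou - rho2 / c2 - alpha * v)


def ciou_t(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Differentiable CIoU of predicted boxes [M, 4] against constants [M, 4].

    The aspect-ratio trade-off coefficient alpha is treated as a constant
    during backpropagation, following the loss's reference treatment.
    """
    t = target.astype(np.float32)
    px1, py1, px2, py2 = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    tx1, ty1, tx2, ty2 = (Tensor(t[:, i]) for i in range(4))
    iw = px2.minimum(tx2) - px1.maximum(tx1)
    ih = py2.minimum(ty2) - py1.maximum(ty1)
    inter = iw.maximum(0.0) * ih.maximum(0.0)
    area_p = (px2 - px1) * (py2 - py1)
    area_t = Tensor((t[:, 2] - t[:, 0]) * (t[:, 3] - t[:, 1]))
    union = area_p + area_t - inter
    iou = inter / (union + eps)
    cw = px2.maximum(tx2) - px1.minimum(tx1)
    ch = py2.maximum(ty2) - py1.minimum(ty1)
    c2 = cw * cw + ch * ch + eps
    rho2 = ((px1 + px2 - tx1 - tx2) ** 2 + (py1 + py2 - ty1 - ty2) ** 2) * 0.25
    ar_t = np.arctan((t[:, 2] - t[:, 0]) / (t[:, 3] - t[:, 1] + 1e-12))
    v = ((Tensor(ar_t) - ((px2 - px1) / (py2 - py1 + eps)).arctan()) ** 2) \
        * (4.0 / math.pi ** 2)
    alpha = Tensor(v.data / (1.0 - iou.data + v.data + eps))   # no grad through alpha
    return iou - rho2 / c2 - alpha * v


# ---------------------------------------------------------------------------
# Distribution focal loss
# ---------------------------------------------------------------------------

def dfl_targets(target_offset: np.ndarray, reg_max: int) -> np.ndarray:
    """Two-bin bracketing target distribution [M, reg_max] for offsets [M]."""
    t = np.asarray(target_offset, dtype=np.float64)
    if (t < 0).any() or (t > reg_max - 1).any():
        warnings.warn("DFL target offset outside bin range; clamping")
        t = t.clip(0, reg_max - 1)
    lo = np.floor(t).clip(0, reg_max - 1).astype(np.int64)
    hi = np.minimum(lo + 1, reg_max - 1)
    w_hi = t - lo
    w_lo = 1.0 - w_hi
    out = np.zeros((t.size, reg_max))
    np.add.at(out, (np.arange(t.size), lo), w_lo)
    np.add.at(out, (np.arange(t.size), hi), w_hi)
    return out


def dfl_loss(dist_logits, target_offset) -> float:
    """Weighted cross-entropy against the bracketing-bin target.

    dist_logits: [reg_max] or [M, reg_max]; target_offset: scalar or [M].
    Returns the mean per-row loss.
    """
    z = np.atleast_2d(np.asarray(dist_logits, dtype=np.float64))
    t = np.atleast_1d(np.asarray(target_offset, dtype=np.float64))
    probs = dfl_targets(t, z.shape[1])
    zmax = z.max(axis=1, keepdims=True)
    logp = z - zmax - np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    return float(-(probs * logp).sum(axis=1).mean())


# ---------------------------------------------------------------------------
# Composite loss
# ---------------------------------------------------------------------------

class DetectionLoss:
    """Assignment-conditioned composite loss for one image batch.

    cls_mode "normalized" (default) scores every anchor-class pair against
    the soft target map and divides by the target-score sum — the scaling
    that keeps the classification term stable across anchor counts.
    cls_mode "matched_sum" is the literal unnormalised sum over matched
    anchors only.
    """

    def __init__(self, n_classes: int, reg_max: int = 16,
                 cls_mode: str = "normalized"):
        if cls_mode not in ("normalized", "matched_sum"):
            raise ValueError(cls_mode)
        self.n_classes = n_classes
        self.reg_max = reg_max
        self.cls_mode = cls_mode

    def __call__(self, cls_logits: Tensor, box_logits: Tensor,
                 anchor_points: np.ndarray, strides: np.ndarray,
                 assignments: list[TargetAssignment], gts: list
                 ) -> tuple[Tensor, LossBreakdown]:
        """cls_logits [B, A, nc]; box_logits [B, A, 4, reg_max]."""
        from .head import decode_boxes_t
        B, A, _ = cls_logits.data.shape
        tss = max(sum(a.target_scores.sum() for a in assignments), 1.0)

        target_map = np.stack([a.target_scores for a in assignments]).astype(np.float32)
        b_idx, a_idx, tboxes, weights = [], [], [], []
        for bi, (asgn, gt) in enumerate(zip(assignments, gts)):
            if asgn.n_matched == 0:
                continue
            b_idx.append(np.full(asgn.n_matched, bi))
            a_idx.append(asgn.anchor_idx)
            tboxes.append(gt.boxes[asgn.gt_idx])
            weights.append(asgn.box_weight)

        zero = Tensor(np.zeros(()), requires_grad=False)
        if b_idx:
            b_idx = np.concatenate(b_idx)
            a_idx = np.concatenate(a_idx)
            tboxes = np.concatenate(tboxes)
            weights = np.concatenate(weights).astype(np.float32)
            matched_logits = box_logits[b_idx, a_idx]           # [M, 4, reg_max]
            pb = decode_boxes_t(matched_logits, anchor_points[a_idx],
                                strides[a_idx])                 # [M, 4]
            box_term = ((1.0 - ciou_t(pb, tboxes)) * Tensor(weights)).sum() \
                * (1.0 / tss)
            # dfl on the matched anchors' side offsets, in stride units
            s = strides[a_idx]
            lt = (anchor_points[a_idx] - tboxes[:, :2]) / s[:, None]
            rb = (tboxes[:, 2:] - anchor_points[a_idx]) / s[:, None]
            offsets = np.concatenate([lt, rb], axis=1).clip(0, self.reg_max - 1 - 1e-3)
            logits = matched_logits.reshape(-1, self.reg_max)
            probs = dfl_targets(offsets.reshape(-1), self.reg_max)
            w4 = np.repeat(weights / 4.0, 4)  # mean over the four sides
            dfl_term = T.softmax_cross_entropy(logits, probs, w4) * (1.0 / tss)
        else:
            box_term = zero
            dfl_term = zero

        if self.cls_mode == "normalized":
            cls_term = T.bce_with_logits(cls_logits, target_map) * (1.0 / tss)
        else:
            if b_idx is not None and len(np.atleast_1d(b_idx)):
                logits_m = cls_logits[b_idx, a_idx]
                cls_term = T.bce_with_logits(logits_m, target_map[b_idx, a_idx])
            else:
                cls_term = zero

        total = box_term * BOX_WEIGHT + cls_term * CLS_WEIGHT + dfl_term * DFL_WEIGHT
        bx, cl, df = float(box_term.data), float(cls_term.data), float(dfl_term.data)
        breakdown = LossBreakdown(bx, cl, df,
                                  BOX_WEIGHT * bx + CLS_WEIGHT * cl + DFL_WEIGHT * df,
                                  float(tss))
        return total, breakdown
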