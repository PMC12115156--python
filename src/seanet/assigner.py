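"""Task-aligned assignment of anchor points to ground-truth boxes.

Each ground-truth box selects its top-k candidate anchors by the
alignment metric  score(class)^alpha * IoU^beta  among anchors whose
centre lies inside the box; an anchor claimed by several boxes goes to
the one it overlaps most. Matched anchors receive a soft target score —
the alignment metric rescaled so that each box's best anchor scores that
box's best IoU — which also serves as the box-regression weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boxes import BoxSet, iou_matrix


@dataclass
class TargetAssignment:
    matches: list[tuple[int, int]]          # (anchor index, gt index)
    target_scores: np.ndarray               # [A, n_classes] in [0, 1]
    box_weight: np.ndarray                  # [M] weights of matched anchors
    n_matched: int

    @property
    def anchor_idx(self) -> np.ndarray:
        return np.array([a for a, _ in self.matches], dtype=np.int64)

    @property
    def gt_idx(self) -> np.ndarray:
        return np.array([g for _, g in self.matches], dtype=np.int64)


class TaskAlignedAssigner:
    def __init__(self, topk: int = 10, alpha: float = 0.5, beta: float = 6.0,
                 eps: float = 1e-9):
        self.topk = topk
        self.alpha = alpha
        self.beta = beta
        self.eps = eps

    def __call__(self, pred_scores: np.ndarray, pred_boxes: np.ndarray,
                 anchor_points: np.ndarray, gt: BoxSet, n_classes: int
                 ) -> TargetAssignment:
        A = pred_scores.shape[0]
        G = len(gt)
        target_scores = np.zeros((A, n_classes), dtype=np.float64)
        if G == 0:
            return TargetAssignment([], target_scores, np.zeros(0), 0)

        # candidate mask: anchor centre inside the gt box
        px, py = anchor_points[:, 0], anchor_points[:, 1]
        inside = ((px[None, :] > gt.boxes[:, 0, None]) &
                  (px[None, :] < gt.boxes[:, 2, None]) &
                  (py[None, :] > gt.boxes[:, 1, None]) &
                  (py[None, :] < gt.boxes[:, 3, None]))          # [G, A]
        iou = iou_matrix(gt.boxes, pred_boxes).clip(0)           # [G, A]
        cls_prob = pred_scores[:, gt.classes].T.clip(self.eps)   # [G, A]
        metric = (cls_prob ** self.alpha) * (iou ** self.beta)
        metric = np.where(inside, metric, 0.0)

        # top-k candidates per gt
        selected = np.zeros_like(metric, dtype=bool)
        k = min(self.topk, A)
        top = np.argpartition(-metric, kth=k - 1, axis=1)[:, :k]
        rows = np.repeat(np.arange(G), k)
        cand = metric[rows, top.ravel()] > 0
        selected[rows[cand], top.ravel()[cand]] = True

        # resolve anchors claimed by multiple gts: keep the highest-IoU gt
        claimed = selected.sum(axis=0) > 1
        if claimed.any():
            best_gt = iou.argmax(axis=0)
            for a in np.flatnonzero(claimed):
                selected[:, a] = False
                selected[best_gt[a], a] = True

        # normalised soft targets
        metric_sel = np.where(selected, metric, 0.0)
        iou_sel = np.where(selected, iou, 0.0)
        max_metric = metric_sel.max(axis=1, keepdims=True)
        max_iou = iou_sel.max(axis=1, keepdims=True)
        norm = metric_sel * max_iou / (max_metric + self.eps)    # [G, A]

        matches = []
        weights = []
        gs, as_ = np.nonzero(selected)
        order = np.argsort(as_)
        for g, a in zip(gs[order], as_[order]):
            t = norm[g, a]
            target_scores[a, gt.classes[g]] = t
            matches.append((int(a), int(g)))
            weights.append(t)
        return TargetAssignment(matches, target_scores,
                                np.array(weights, dtype=np.float64), len(matches))
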