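"""Axis-aligned boxes in pixel coordinates, half-open [min, max)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BoxSet:
    """Boxes [N, 4] as (x_min, y_min, x_max, y_max), class ids, optional scores."""

    boxes: np.ndarray
    classes: np.ndarray
    scores: np.ndarray | None = None

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 4)
        self.classes = np.asarray(self.classes, dtype=np.int64).reshape(-1)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=np.float64).reshape(-1)

    def __len__(self):
        return self.boxes.shape[0]

    @staticmethod
    def empty() -> "BoxSet":
        return BoxSet(np.zeros((0, 4)), np.zeros(0, dtype=np.int64), np.zeros(0))


def box_areas(boxes: np.ndarray) -> np.ndarray:
    return (boxes[:, 2] - boxes[:, 0]).clip(0) * (boxes[:, 3] - boxes[:, 1]).clip(0)


def iou_matrix(a: np.ndarray, b: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Pairwise IoU of boxes a [N, 4] vs b [M, 4] -> [N, M]."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = (br - tl).clip(0)
    inter = wh[..., 0] * wh[..., 1]
    union = box_areas(a)[:, None] + box_areas(b)[None, :] - inter
    return inter / (union + eps)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float = 0.7,
        max_det: int = 300) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, score-ordered."""
    order = np.argsort(-scores)
    keep = []
    while order.size and len(keep) < max_det:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        ious = iou_matrix(boxes[i:i + 1], boxes[order[1:]])[0]
        order = order[1:][ious <= iou_threshold]
    return np.array(keep, dtype=np.int64)
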