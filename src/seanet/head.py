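"""Anchor-free detection head with distribution-based box regression.

Each pyramid level predicts, at every cell, class logits and — per box
side (left, top, right, bottom) — a discrete distribution over
``reg_max`` offset bins in stride units. Boxes are decoded as the
softmax expectation of each side's distribution, scaled by the stride
and measured from the cell centre.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .layers import Conv2d, Module, Sequential, cbs
from .tensor import Tensor


def make_anchors(shapes, strides, offset: float = 0.5):
    """Anchor-point centres (pixels) and per-anchor strides.

    shapes: [(H, W)] per level; strides: per level. Returns
    points [A, 2] and stride [A].
    """
    pts, sts = [], []
    for (h, w), s in zip(shapes, strides):
        ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        grid = np.stack([(xs + offset) * s, (ys + offset) * s], axis=-1)
        pts.append(grid.reshape(-1, 2))
        sts.append(np.full(h * w, s, dtype=np.float64))
    return np.concatenate(pts).astype(np.float64), np.concatenate(sts)


def decode_boxes_np(dist_logits: np.ndarray, anchor_points: np.ndarray,
                    strides: np.ndarray, image_size: tuple[int, int] | None = None
                    ) -> np.ndarray:
    """Decode [A, 4, reg_max] side distributions to [A, 4] pixel boxes.

    Expectation of each side's softmax distribution gives the offset in
    stride units; optionally clips to (W, H) image bounds.
    """
    z = dist_logits - dist_logits.max(axis=-1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=-1, keepdims=True)
    bins = np.arange(dist_logits.shape[-1], dtype=np.float64)
    d = (p * bins).sum(axis=-1) * strides[:, None]     # [A, 4] l,t,r,b in px
    boxes = np.stack([anchor_points[:, 0] - d[:, 0],
                      anchor_points[:, 1] - d[:, 1],
                      anchor_points[:, 0] + d[:, 2],
                      anchor_points[:, 1] + d[:, 3]], axis=1)
    if image_size is not None:
        w, h = image_size
        boxes[:, 0::2] = boxes[:, 0::2].clip(0, w)
        boxes[:, 1::2] = boxes[:, 1::2].clip(0, h)
    return boxes


def decode_boxes_t(dist_logits: Tensor, anchor_points: np.ndarray,
                   strides: np.ndarray) -> Tensor:
    """Differentiable decode of [M, 4, reg_max] logits to [M, 4] boxes."""
    p = T.softmax(dist_logits, axis=-1)
    bins = np.arange(dist_logits.shape[-1], dtype=np.float32)
    d = (p * Tensor(bins)).sum(axis=-1) * Tensor(strides[:, None].astype(np.float32))
    ax = anchor_points[:, 0].astype(np.float32)
    ay = anchor_points[:, 1].astype(np.float32)
    return T.stack([Tensor(ax) - d[:, 0], Tensor(ay) - d[:, 1],
                    Tensor(ax) + d[:, 2], Tensor(ay) + d[:, 3]], axis=1)


class DetectionHead(Module):
    """Per-level conv towers for classification and box-distribution logits."""

    def __init__(self, in_widths, n_classes: int, reg_max: int = 16, rng=None):
        super().__init__()
        self.n_classes = n_classes
        self.reg_max = reg_max
        self.cls_towers, self.box_towers = [], []
        for w in in_widths:
            hidden = max(w, 16)
            cls_out = Conv2d(hidden, n_classes, 1, rng=rng)
            # bias init so initial foreground probability is ~1% (stable BCE)
            cls_out.bias.data[:] = -4.595
            box_out = Conv2d(hidden, 4 * reg_max, 1, rng=rng)
            self.cls_towers.append((Sequential(cbs(w, hidden, 3, rng=rng),
                                               cbs(hidden, hidden, 3, rng=rng)),
                                    cls_out))
            self.box_towers.append((Sequential(cbs(w, hidden, 3, rng=rng),
                                               cbs(hidden, hidden, 3, rng=rng)),
                                    box_out))

    def forward(self, features):
        """features: per-level [B, C, H, W] -> (cls [B, A, nc], box [B, A, 4, reg_max],
        anchor points [A, 2], strides [A])."""
        cls_flat, box_flat, shapes = [], [], []
        B = features[0].data.shape[0]
        for f, (cstem, cout), (bstem, bout) in zip(
                features, self.cls_towers, self.box_towers):
            shapes.append(f.data.shape[2:])
            c = cout(cstem(f))                     # [B, nc, H, W]
            b = bout(bstem(f))                     # [B, 4*reg_max, H, W]
            h, w = f.data.shape[2:]
            cls_flat.append(c.reshape(B, self.n_classes, h * w).transpose(0, 2, 1))
            box_flat.append(b.reshape(B, 4, self.reg_max, h * w).transpose(0, 3, 1, 2))
        cls = T.concat(cls_flat, axis=1)
        box = T.concat(box_flat, axis=1)
        strides = [8 * 2 ** i for i in range(len(features))]
        pts, sts = make_anchors(shapes, strides)
        return cls, box, pts, sts
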