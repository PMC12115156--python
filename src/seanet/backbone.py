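"""Staged convolutional backbone with the detail-amplification stage.

A compact layer-aggregation backbone in the efficient-aggregation (GELAN)
style: a stride-2 stem, then four downsampling stages built from CSP-style
split-transform-merge blocks. The stage producing stride-4 features — the
second stage, where fine texture is still resolved — is replaced by the
multi-scale detail amplification module (MDAM). Taps are exposed at
strides 8, 16 and 32 for the pyramid neck.

Input images are [B, 3, H, W] with values in [0, 1]; H and W must be
divisible by 32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import tensor as T
from .attention import BottleRep
from .layers import Module, Sequential, cbs
from .mdam import MDAM, MDAMConfig
from .tensor import Tensor


@dataclass
class BackboneConfig:
    # widths for strides (2, 4, 8, 16, 32) before width_mult
    stage_widths: tuple[int, ...] = (32, 48, 64, 128, 256)
    stage_depths: tuple[int, ...] = (1, 1, 1, 1)
    width_mult: float = 1.0
    mdam_stage_index: int = 2       # 1-based; stage 2 produces stride-4 maps
    use_mdam: bool = True
    branch_kernels: tuple[int, int, int] = (3, 5, 7)

    def scaled_widths(self) -> tuple[int, ...]:
        def r4(w):  # round to a multiple of 4 so MDAM branch widths divide
            return max(int(round(w * self.width_mult / 4)) * 4, 4)
        return tuple(r4(w) for w in self.stage_widths)


class CSPBlock(Module):
    """Split-transform-merge aggregation: half the channels pass through a
    chain of residual blocks, the other half skip; a 1x1 conv merges."""

    def __init__(self, channels: int, depth: int = 1, rng=None):
        super().__init__()
        half = max(channels // 2, 4)
        self.split_a = cbs(channels, half, 1, rng=rng)
        self.split_b = cbs(channels, half, 1, rng=rng)
        self.blocks = [BottleRep(half, half, rng=rng) for _ in range(depth)]
        self.merge = cbs(2 * half, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        a = self.split_a(x)
        b = self.split_b(x)
        for blk in self.blocks:
            b = blk(b)
        return self.merge(T.concat([a, b], axis=1))


class Backbone(Module):
    def __init__(self, cfg: BackboneConfig, rng=None):
        super().__init__()
        self.cfg = cfg
        ws = cfg.scaled_widths()
        if len(ws) != 5:
            raise ValueError("stage_widths must give widths for strides 2..32")
        if not (1 <= cfg.mdam_stage_index <= 5):
            raise ValueError("mdam_stage_index must address one of stages 1-5")
        depths = cfg.stage_depths
        self.stem = cbs(3, ws[0], 3, stride=2, rng=rng)  # stage 1, stride 2
        self.stages = []
        in_w = ws[0]
        for si, w in enumerate(ws[1:], start=2):  # stages 2..5 -> strides 4..32
            down = cbs(in_w, w, 3, stride=2, rng=rng)
            if cfg.use_mdam and si == cfg.mdam_stage_index:
                body = MDAM(MDAMConfig(w, w, branch_kernels=cfg.branch_kernels),
                            rng=rng)
            else:
                body = CSPBlock(w, depth=depths[si - 2], rng=rng)
            self.stages.append(Sequential(down, body))
            in_w = w
        self.tap_widths = (ws[2], ws[3], ws[4])

    def forward(self, images: Tensor):
        B, C, H, W = images.data.shape
        if C != 3:
            raise ValueError("expected RGB input [B, 3, H, W]")
        if H % 32 or W % 32:
            raise ValueError(
                f"input spatial dims must be divisible by 32 (got {H}x{W}); "
                "letterbox-pad the image first")
        x = self.stem(images)
        taps = []
        for i, stage in enumerate(self.stages):
            x = stage(x)
            if i >= 1:  # stages 3..5 produce strides 8/16/32
                taps.append(x)
        return tuple(taps)  # (P4, P6, P9)
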