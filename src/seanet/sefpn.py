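"""Semantic Enhancement Feature Pyramid (SE-FPN).

Fuses the three backbone taps (strides 8/16/32) through four Contrast
Enhancement Module nodes in a top-down then bottom-up pass. Fusion is
plain channel concatenation — no learned fusion weights — followed by a
CEM node:

    U4 = CEM(concat(P6, up(P9)))          stride 16, intermediate
    D1 = CEM(concat(P4, up(U4)))          stride 8
    D2 = CEM(concat(down(D1), U4, P6))    stride 16  (backbone skip)
    D3 = CEM(concat(down(D2), P9))        stride 32

Cross-scale alignment uses nearest-neighbour x2 upsampling + 1x1 conv
block on the way up and a stride-2 3x3 conv block on the way down.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .attention import CEM
from .layers import Module, Sequential, cbs
from .tensor import Tensor


class _Upsample2x(Module):
    def forward(self, x):
        return T.upsample_nearest2x(x)


class Align(Module):
    """Align a feature map from source_stride to target_stride/target_width.

    Each factor-of-two hop is one upsample (+1x1 conv block) or one
    stride-2 3x3 conv block; equal strides use a 1x1 conv block only.
    """

    def __init__(self, in_width: int, source_stride: int, target_stride: int,
                 target_width: int, rng=None):
        super().__init__()
        if source_stride < 1 or target_stride < 1 or \
                (source_stride & (source_stride - 1)) or \
                (target_stride & (target_stride - 1)):
            raise ValueError("strides must be powers of two")
        mods = []
        stride, width = source_stride, in_width
        while stride > target_stride:  # upsample hops
            mods.append(_Upsample2x())
            mods.append(cbs(width, target_width, 1, rng=rng))
            width = target_width
            stride //= 2
        while stride < target_stride:  # downsample hops
            mods.append(cbs(width, target_width, 3, stride=2, rng=rng))
            width = target_width
            stride *= 2
        if not mods:
            mods.append(cbs(width, target_width, 1, rng=rng))
        self.ops = Sequential(*mods)

    def forward(self, x):
        return self.ops(x)


class SEFPN(Module):
    """Three-level pyramid neck; see module docstring for the wiring."""

    STRIDES = (8, 16, 32)

    def __init__(self, in_widths: tuple[int, int, int],
                 widths: tuple[int, int, int] = (64, 128, 256),
                 width_mult: float = 1.0, cem_repeats: int = 3, rng=None):
        super().__init__()
        w4, w6, w9 = (max(int(round(w * width_mult)), 4) for w in widths)
        self.widths = (w4, w6, w9)
        i4, i6, i9 = in_widths
        self.up_p9 = Align(i9, 32, 16, w6, rng=rng)
        self.cem_u4 = CEM(i6 + w6, w6, n_reps=cem_repeats, rng=rng)
        self.up_u4 = Align(w6, 16, 8, w4, rng=rng)
        self.cem_d1 = CEM(i4 + w4, w4, n_reps=cem_repeats, rng=rng)
        self.down_d1 = Align(w4, 8, 16, w6, rng=rng)
        self.cem_d2 = CEM(w6 + w6 + i6, w6, n_reps=cem_repeats, rng=rng)
        self.down_d2 = Align(w6, 16, 32, w9, rng=rng)
        self.cem_d3 = CEM(w9 + i9, w9, n_reps=cem_repeats, rng=rng)

    @property
    def cem_nodes(self):
        return [self.cem_u4, self.cem_d1, self.cem_d2, self.cem_d3]

    def forward(self, p4: Tensor, p6: Tensor, p9: Tensor):
        for a, b in ((p4, p6), (p6, p9)):
            if a.data.shape[2] != 2 * b.data.shape[2] or \
                    a.data.shape[3] != 2 * b.data.shape[3]:
                raise ValueError("pyramid inputs must halve spatially per level")
        u4 = self.cem_u4(T.concat([p6, self.up_p9(p9)], axis=1))
        d1 = self.cem_d1(T.concat([p4, self.up_u4(u4)], axis=1))
        d2 = self.cem_d2(T.concat([self.down_d1(d1), u4, p6], axis=1))
        d3 = self.cem_d3(T.concat([self.down_d2(d2), p9], axis=1))
        return d1, d2, d3
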