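"""Contrast-oriented attention blocks of the pyramid neck.

Three pieces assemble into the Contrast Enhancement Module (CEM):

* :class:`SCAM` — a light spatial-channel attention pre-stage (channel
  gating first, spatial gating second).
* :class:`FBC` — fore-background contrast attention. A 1-channel conv +
  batch norm + leaky ReLU followed by a sigmoid yields a foreground
  activation map Ff in (0, 1); the background map is its complement
  Fb = 1 - Ff. Each map is matrix-multiplied against the flattened
  feature map to pool a per-channel descriptor (vf, vb: [B, 1, C]),
  each descriptor is gated through an affine map + sigmoid (cf, cb), and
  the block's output rescales the input channels by the gate *difference*:
  F' = F * (cf - cb). Channels that respond more to foreground than to
  background are amplified; background-dominated channels are suppressed.
* :class:`BottleRep` — the ubiquitous two-conv residual block with a
  learnable scalar shortcut weight.

CEM: x <- SCAM(x); y1 <- CBS1(x); y1 <- FBC(y1) + y1; y2 <- CBS2(x);
collect [y1] then three successive BottleRep outputs of y2; a final CBS
fuses the channel concatenation.

Convolution blocks here use batch norm + SiLU.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .layers import (BatchNorm2d, Conv2d, LeakyReLU, Module, Parameter,
                     Sequential, cbs)
from .tensor import Tensor


class SCAM(Module):
    """Spatial-channel attention: channel gate, then spatial gate.

    Channel attention pools the map globally by average and by max, pushes
    both descriptors through a shared two-layer bottleneck, sums and
    squashes; spatial attention convolves the channelwise mean/max maps
    with a 7x7 kernel. The two gates are applied sequentially.
    """

    def __init__(self, channels: int, reduction: int = 4, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        hidden = max(channels // reduction, 1)
        self.fc1 = Conv2d(channels, hidden, 1, rng=rng)
        self.fc2 = Conv2d(hidden, channels, 1, rng=rng)
        self.spatial = Conv2d(2, 1, 7, rng=rng)

    def channel_gate(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3), keepdims=True)
        mx = x.max(axis=(2, 3), keepdims=True)
        z = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return z.sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        x = x * self.channel_gate(x)
        mean_map = x.mean(axis=1, keepdims=True)
        max_map = x.max(axis=1, keepdims=True)
        gate_s = self.spatial(T.concat([mean_map, max_map], axis=1)).sigmoid()
        return x * gate_s


class FBC(Module):
    """Fore-background contrast attention (see module docstring).

    shared_gate ties the foreground and background affine gates to one
    map (the symmetric reading); by default they are independent, which
    lets training break the fore/background symmetry.
    """

    def __init__(self, channels: int, shared_gate: bool = False, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.channels = channels
        self.cblr = Sequential(Conv2d(channels, 1, 1, rng=rng),
                               BatchNorm2d(1), LeakyReLU(0.1))
        self.rho_f = Conv2d(channels, channels, 1, rng=rng)
        self.rho_b = self.rho_f if shared_gate else Conv2d(channels, channels, 1, rng=rng)
        self.shared_gate = shared_gate

    def activation_maps(self, x: Tensor) -> tuple[Tensor, Tensor]:
        ff = self.cblr(x).sigmoid()          # [B, 1, H, W]
        return ff, 1.0 - ff

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.data.shape
        if C != self.channels:
            raise ValueError(f"FBC built for {self.channels} channels, got {C}")
        if H * W == 0:
            raise ValueError("empty spatial extent")
        ff, fb = self.activation_maps(x)
        ft = x.reshape(B, C, H * W).transpose(0, 2, 1)       # [B, HW, C]
        vf = ff.reshape(B, 1, H * W) @ ft                    # [B, 1, C]
        vb = fb.reshape(B, 1, H * W) @ ft
        cf = self._gate(self.rho_f, vf)
        cb = self._gate(self.rho_b, vb)
        scale = (cf - cb).reshape(B, C, 1, 1)
        return x * scale

    @staticmethod
    def _gate(rho: Conv2d, v: Tensor) -> Tensor:
        B, _, C = v.data.shape
        return rho(v.transpose(0, 2, 1).reshape(B, C, 1, 1)) \
            .reshape(B, C).sigmoid().reshape(B, 1, C)

    def descriptors(self, x: Tensor):
        """Return (vf, vb, cf, cb) for inspection/testing."""
        B, C, H, W = x.data.shape
        ff, fb = self.activation_maps(x)
        ft = x.reshape(B, C, H * W).transpose(0, 2, 1)
        vf = ff.reshape(B, 1, H * W) @ ft
        vb = fb.reshape(B, 1, H * W) @ ft
        return vf, vb, self._gate(self.rho_f, vf), self._gate(self.rho_b, vb)


class BottleRep(Module):
    """Two 3x3 conv blocks with a learnable scalar-weighted identity shortcut."""

    def __init__(self, in_ch: int, out_ch: int, rng=None):
        super().__init__()
        self.conv1 = cbs(in_ch, out_ch, 3, rng=rng)
        self.conv2 = cbs(out_ch, out_ch, 3, rng=rng)
        self.shortcut = in_ch == out_ch
        self.alpha = Parameter(np.ones(1)) if self.shortcut else None

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv2(self.conv1(x))
        if self.shortcut:
            y = y + x * self.alpha
        return y


class CEM(Module):
    """Contrast Enhancement Module: SCAM, an FBC residual branch, and a
    chain of BottleRep blocks fused by a final conv block."""

    def __init__(self, in_ch: int, out_ch: int, hidden: int | None = None,
                 n_reps: int = 3, rng=None):
        super().__init__()
        hidden = hidden or max(out_ch // 2, 4)
        self.hidden = hidden
        self.n_reps = n_reps
        self.scam = SCAM(in_ch, rng=rng)
        self.cbs1 = cbs(in_ch, hidden, 1, rng=rng)
        self.cbs2 = cbs(in_ch, hidden, 1, rng=rng)
        self.fbc = FBC(hidden, rng=rng)
        self.reps = [BottleRep(hidden, hidden, rng=rng) for _ in range(n_reps)]
        self.cbs3 = cbs((1 + n_reps) * hidden, out_ch, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.scam(x)
        y1 = self.cbs1(x)
        y1 = self.fbc(y1) + y1
        y2 = self.cbs2(x)
        mid_out = [y1]
        for rep in self.reps:
            y2 = rep(y2)
            mid_out.append(y2)
        return self.cbs3(T.concat(mid_out, axis=1))
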