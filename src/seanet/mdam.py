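"""Multi-Scale Detail Amplification Module (MDAM).

A five-branch block placed early in the backbone to widen the receptive
field where fine texture detail still survives — the regime that matters
when aquatic targets differ from the background only in subtle local
structure. Branch 1 carries the reduced input through unchanged; branches
2–4 stack an asymmetric k x 1 / 1 x k pair with a 3 x 3 convolution dilated
at rate k (k = 3, 5, 7 by default, i.e. k_i = 2i - 1 for branch index i);
branch 5 taps the *original* input through a 1 x 1 block so un-reduced
local detail is retained. The concatenation of branches 2–5 is added
elementwise to branch 1 and a final 3 x 3 block maps to the output width.

Convolution blocks in this module use group normalisation + ReLU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import tensor as T
from .layers import Module, Sequential, cbs


@dataclass
class MDAMConfig:
    """Configuration of the five-branch amplification block.

    branch_kernels are the (k2, k3, k4) asymmetric kernel lengths, which
    double as the dilation rates of each branch's dilated convolution.
    """

    in_channels: int
    out_channels: int
    reduced_channels: int | None = None
    branch_kernels: tuple[int, int, int] = (3, 5, 7)
    dilated_kernel_size: int = 3
    norm_groups: int = 8
    norm: str = "group"  # "group" or "none" (norm-free diagnostic mode)

    def __post_init__(self):
        if self.reduced_channels is None:
            self.reduced_channels = self.in_channels
        if self.in_channels < 1 or self.out_channels < 1 or self.reduced_channels < 1:
            raise ValueError("channel widths must be positive")
        if self.reduced_channels % 4 != 0:
            raise ValueError(
                f"reduced_channels must be divisible by 4 (branches 2-5 each emit "
                f"reduced_channels/4); got {self.reduced_channels}")
        for k in (*self.branch_kernels, self.dilated_kernel_size):
            if k < 3 or k % 2 == 0:
                raise ValueError(f"branch kernels must be odd and >= 3; got {k}")


def mdam_receptive_field(cfg: MDAMConfig) -> dict[int, int]:
    """Analytic one-axis receptive-field extent of branches 2-4.

    Sequential convolutions telescope: extents add as (k_eff - 1) each.
    Per branch (through the whole module): the shared 1x1 adds 0, the
    asymmetric k x 1 / 1 x k pair adds k - 1 per axis, the 3x3 convolution
    dilated at rate k adds d * (3 - 1) = 2k, and the final 3x3 adds 2 —
    a total extent of 1 + (k - 1) + 2k + 2 = 3k + 2.
    """
    d = cfg.dilated_kernel_size
    return {i + 2: 1 + (k - 1) + k * (d - 1) + 2
            for i, k in enumerate(cfg.branch_kernels)}


class MDAM(Module):
    """See module docstring. Output keeps the input's spatial dims."""

    def __init__(self, cfg: MDAMConfig, rng=None):
        super().__init__()
        self.cfg = cfg
        rng = rng or np.random.default_rng()
        c_in, c_red = cfg.in_channels, cfg.reduced_channels
        quarter = c_red // 4
        kw = dict(norm=cfg.norm, act="relu", norm_groups=cfg.norm_groups, rng=rng)
        # shared 1x1 reduction consumed by branches 1-4
        self.reduce = cbs(c_in, c_red, 1, **kw)
        self.branches = []
        for k in cfg.branch_kernels:
            self.branches.append(Sequential(
                cbs(c_red, quarter, (k, 1), **kw),
                cbs(quarter, quarter, (1, k), **kw),
                cbs(quarter, quarter, cfg.dilated_kernel_size, dilation=k, **kw),
            ))
        # branch 5: 1x1 on the original input, keeping raw local detail
        self.branch5 = cbs(c_in, quarter, 1, **kw)
        self.out = cbs(c_red, cfg.out_channels, 3, **kw)
        # concat(Br2..Br5) must match Br1's width for the elementwise add
        assert 3 * quarter + quarter == c_red

    def forward(self, x: T.Tensor) -> T.Tensor:
        if not np.isfinite(x.data).all():
            raise ValueError("MDAM input contains non-finite values")
        if x.data.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} channels, got {x.data.shape[1]}")
        xr = self.reduce(x)  # x' in the branch equations
        br1 = xr
        outs = [b(xr) for b in self.branches]
        outs.append(self.branch5(x))
        fused = br1 + T.concat(outs, axis=1)
        return self.out(fused)
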