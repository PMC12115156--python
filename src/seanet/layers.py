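"""Neural-network layers on top of the autodiff core.

Two convolution-block flavours appear throughout the detector and are kept
distinct on purpose: the backbone's detail-amplification stage normalises
with group norm and rectifies with ReLU, while the pyramid/neck blocks use
batch norm with SiLU. :func:`cbs` builds either.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container with parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    @staticmethod
    def _children(value, name):
        """Yield (name, Parameter|Module) pairs, recursing through
        arbitrarily nested lists/tuples."""
        if isinstance(value, (Parameter, Module)):
            yield name, value
        elif isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                yield from Module._children(item, f"{name}.{i}")

    def modules(self):
        yield self
        for k, v in self.__dict__.items():
            for _, child in Module._children(v, k):
                if isinstance(child, Module):
                    yield from child.modules()

    def named_parameters(self, prefix=""):
        for k, v in self.__dict__.items():
            for name, child in Module._children(v, f"{prefix}{k}"):
                if isinstance(child, Parameter):
                    yield name, child
                elif isinstance(child, Module):
                    yield from child.named_parameters(f"{name}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- flat serialization (weights + buffers) ---------------------------
    def state_dict(self) -> dict:
        out = {name: p.data for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            out[name] = buf
        return out

    def named_buffers(self, prefix=""):
        for k, v in self.__dict__.items():
            if isinstance(v, np.ndarray) and k.startswith("running_"):
                yield f"{prefix}{k}", v
                continue
            for name, child in Module._children(v, f"{prefix}{k}"):
                if isinstance(child, Module):
                    yield from child.named_buffers(f"{name}.")

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data = np.asarray(value, dtype=T.DTYPE).reshape(params[name].data.shape)
            elif name in bufs:
                bufs[name][...] = value
            else:
                raise KeyError(f"unknown parameter in checkpoint: {name}")


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size, stride=1,
                 padding="same", dilation=1, bias=True, rng=None):
        super().__init__()
        kh, kw = _pair(kernel_size)
        self.stride = _pair(stride)
        self.dilation = _pair(dilation)
        if padding == "same":
            # output spatial = ceil(input / stride)
            self.padding = (self.dilation[0] * (kh - 1) // 2,
                            self.dilation[1] * (kw - 1) // 2)
        else:
            self.padding = _pair(padding)
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kh * kw
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(rng.normal(0.0, std, size=(out_ch, in_ch, kh, kw)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, self.stride,
                        self.padding, self.dilation)


class GroupNorm(Module):
    """Group norm; the group count is clipped to a divisor of the width."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        super().__init__()
        g = min(groups, channels)
        while channels % g != 0:
            g -= 1
        self.groups = g
        self.eps = eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))

    def forward(self, x):
        return T.group_norm(x, self.weight, self.bias, self.groups, self.eps)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=T.DTYPE)
        self.running_var = np.ones(channels, dtype=T.DTYPE)

    def forward(self, x):
        return T.batch_norm(x, self.weight, self.bias, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.1):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = float(np.sqrt(1.0 / in_f))
        self.weight = Parameter(rng.uniform(-std, std, size=(in_f, out_f)))
        self.bias = Parameter(np.zeros(out_f)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


def cbs(in_ch: int, out_ch: int, kernel_size=3, stride=1, dilation=1,
        norm: str = "batch", act: str = "silu", norm_groups: int = 8,
        rng=None) -> Sequential:
    """Conv + normalisation + activation block.

    norm: "batch" (batch norm), "group" (group norm) or "none";
    act: "silu", "relu", "leaky" or "none".
    """
    conv = Conv2d(in_ch, out_ch, kernel_size, stride=stride, dilation=dilation,
                  bias=(norm == "none"), rng=rng)
    norms = {"batch": lambda: BatchNorm2d(out_ch),
             "group": lambda: GroupNorm(out_ch, norm_groups),
             "none": Identity}
    acts = {"silu": SiLU, "relu": ReLU, "leaky": LeakyReLU, "none": Identity}
    return Sequential(conv, norms[norm](), acts[act]())
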