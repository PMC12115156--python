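"""Stochastic gradient descent with momentum and a warmup-cosine schedule."""

from __future__ import annotations

import math

import numpy as np


class SGD:
    """Classic momentum SGD with decoupled-at-the-gradient weight decay.

    update: v <- momentum * v + (grad + wd * w); w <- w - lr * v
    """

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.937,
                 weight_decay: float = 0.0005):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]
        # decay only multi-dim weights; norm gains and biases are exempt
        # (the standard detector-trainer convention)
        self._decay_mask = [p.data.ndim >= 2 for p in self.params]

    def step(self):
        for p, v, dec in zip(self.params, self._vel, self._decay_mask):
            if p.grad is None:
                continue
            g = p.grad + (self.weight_decay * p.data if dec else 0.0)
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class ModelEMA:
    """Exponential moving average of model parameters.

    The decay ramps up as d * (1 - exp(-step / tau)) so early steps are
    tracked closely; normalisation running statistics are copied through
    directly. Evaluation on the averaged weights is the usual one-stage
    detector convention and stabilises short schedules.
    """

    def __init__(self, model, decay: float = 0.999, tau: float = 500.0):
        self.decay = decay
        self.tau = tau
        self.step = 0
        self.shadow = {k: v.copy() for k, v in model.state_dict().items()}

    def update(self, model):
        self.step += 1
        import math
        d = self.decay * (1.0 - math.exp(-self.step / self.tau))
        for k, v in model.state_dict().items():
            if k.endswith("running_mean") or k.endswith("running_var"):
                self.shadow[k][...] = v
            else:
                s = self.shadow[k]
                s *= d
                s += (1.0 - d) * v

    def copy_to(self, model):
        model.load_state_dict(self.shadow)


def warmup_cosine_lr(step: int, total_steps: int, base_lr: float,
                     warmup_steps: int, final_frac: float = 0.01) -> float:
    """Linear warmup from 0 then cosine decay to final_frac * base_lr."""
    if warmup_steps > 0 and step < warmup_steps:
        return base_lr * (step + 1) / warmup_steps
    span = max(total_steps - warmup_steps, 1)
    t = min(max(step - warmup_steps, 0) / span, 1.0)
    return base_lr * (final_frac + (1 - final_frac) * 0.5 * (1 + math.cos(math.pi * t)))
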