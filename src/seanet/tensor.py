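"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based autodiff core sized for CPU training of compact
convolutional detectors: float32 throughout, convolution lowered to
im2col + BLAS ``tensordot``, and hand-derived backward passes for the
normalisation and classification-loss primitives where composing them
from elementary ops would be slow or numerically fragile.

The public surface mirrors the familiar tensor-library conventions:
:class:`Tensor` wraps an ``ndarray``, records its parents, and
``backward()`` runs the tape in reverse topological order.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(DTYPE, copy=False)
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # ---- construction helpers -------------------------------------------
    @staticmethod
    def _make(data, parents, backward, requires_grad=True):
        out = Tensor(data)
        out.requires_grad = (_GRAD_ENABLED and requires_grad
                             and any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True) if g.base is not None or g.dtype != DTYPE else g.copy()
        else:
            self.grad += g

    # ---- autodiff driver -------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = _as_array(grad).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free tape references so intermediate buffers can be reclaimed
                node._backward = None
                node._prev = ()

    # ---- elementwise arithmetic -----------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data - other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * out_data / other.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), bwd)

    # ---- elementwise functions ------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        out_data = np.log(self.data)

        def bwd(g):
            self._accum(g / self.data)

        return Tensor._make(out_data, (self,), bwd)

    def sqrt(self):
        return self ** 0.5

    def arctan(self):
        out_data = np.arctan(self.data)

        def bwd(g):
            self._accum(g / (1.0 + self.data * self.data))

        return Tensor._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = sigmoid_np(self.data)

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def bwd(g):
            self._accum(g * (self.data > 0))

        return Tensor._make(out_data, (self,), bwd)

    def leaky_relu(self, slope: float = 0.1):
        out_data = np.where(self.data > 0, self.data, slope * self.data)

        def bwd(g):
            self._accum(g * np.where(self.data > 0, 1.0, slope).astype(DTYPE))

        return Tensor._make(out_data, (self,), bwd)

    def silu(self):
        s = sigmoid_np(self.data)
        out_data = self.data * s

        def bwd(g):
            self._accum(g * (s * (1.0 + self.data * (1.0 - s))))

        return Tensor._make(out_data, (self,), bwd)

    def maximum(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = np.maximum(self.data, other.data)
        mask = self.data >= other.data  # ties route to self

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * mask, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~mask, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    def minimum(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = np.minimum(self.data, other.data)
        mask = self.data <= other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * mask, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~mask, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    def clip(self, lo, hi):
        return self.maximum(lo).minimum(hi)

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g.reshape(()), self.data.shape) if not keepdims
                            else np.broadcast_to(g, self.data.shape))
                return
            gg = g
            if not keepdims:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                for a in sorted(a % self.data.ndim for a in axes):
                    gg = np.expand_dims(gg, a)
            self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in ((axis,) if isinstance(axis, int) else axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        full = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == full)
        counts = mask.sum(axis=axis, keepdims=True)

        def bwd(g):
            gg = g
            if not keepdims and axis is not None:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                for a in sorted(a % self.data.ndim for a in axes):
                    gg = np.expand_dims(gg, a)
            elif axis is None and not keepdims:
                gg = np.broadcast_to(g.reshape(()), mask.shape)
            self._accum((mask * gg / counts).astype(DTYPE))

        return Tensor._make(out_data, (self,), bwd)

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        in_shape = self.data.shape

        def bwd(g):
            self._accum(g.reshape(in_shape))

        return Tensor._make(out_data, (self,), bwd)

    def transpose(self, *axes):
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), bwd)

    def pad2d(self, ph: int, pw: int, value: float = 0.0):
        """Zero-pad the two trailing (spatial) axes symmetrically."""
        if ph == 0 and pw == 0:
            return self
        pads = [(0, 0)] * (self.data.ndim - 2) + [(ph, ph), (pw, pw)]
        out_data = np.pad(self.data, pads, constant_values=value)

        def bwd(g):
            sl = tuple([slice(None)] * (self.data.ndim - 2)
                       + [slice(ph, g.shape[-2] - ph), slice(pw, g.shape[-1] - pw)])
            self._accum(g[sl])

        return Tensor._make(out_data, (self,), bwd)

    def matmul(self, other: "Tensor"):
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __matmul__ = matmul


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def sigmoid_np(x: np.ndarray) -> np.ndarray:
    # overflow-free: sigmoid(x) = (1 + tanh(x/2)) / 2
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bwd)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), bwd)


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of a [B, C, H, W] tensor."""
    d = x.data
    out_data = d.repeat(2, axis=-2).repeat(2, axis=-1)

    def bwd(g):
        B, C, H2, W2 = g.shape
        gg = g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
        x._accum(gg)

    return Tensor._make(out_data, (x,), bwd)


def _conv_windows(data: np.ndarray, kh: int, kw: int, sh: int, sw: int,
                  dh: int, dw: int) -> np.ndarray:
    """Strided view [B, C, Ho, Wo, kh, kw] of an already-padded array."""
    from numpy.lib.stride_tricks import sliding_window_view
    keh, kew = dh * (kh - 1) + 1, dw * (kw - 1) + 1
    win = sliding_window_view(data, (keh, kew), axis=(2, 3))
    return win[:, :, ::sh, ::sw, ::dh, ::dw]


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Pointwise convolution as a batched matmul (no window extraction)."""
    B, C, H, W = x.data.shape
    O = w.data.shape[0]
    w2 = w.data.reshape(O, C)
    out_data = (w2 @ x.data.reshape(B, C, H * W)).reshape(B, O, H, W)
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)

    def bwd(g):
        gm = g.reshape(B, O, H * W)
        if w.requires_grad:
            gw = np.einsum("boa,bca->oc", gm, x.data.reshape(B, C, H * W),
                           optimize=True)
            w._accum(gw.reshape(O, C, 1, 1))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum((w2.T @ gm).reshape(B, C, H, W))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, bwd)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=(1, 1), padding=(0, 0), dilation=(1, 1)) -> Tensor:
    """2-D cross-correlation of x [B,Ci,H,W] with w [Co,Ci,kh,kw]."""
    sh, sw = stride
    if w.data.shape[2] == 1 and w.data.shape[3] == 1 and stride == (1, 1) \
            and padding == (0, 0):
        return _conv1x1(x, w, b)
    ph, pw = padding
    dh, dw = dilation
    kh, kw = w.data.shape[2], w.data.shape[3]
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    win = _conv_windows(xp, kh, kw, sh, sw, dh, dw)
    out_data = np.tensordot(win, w.data, axes=([1, 4, 5], [1, 2, 3]))
    out_data = np.ascontiguousarray(out_data.transpose(0, 3, 1, 2))
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)

    H, W = x.data.shape[2], x.data.shape[3]
    keh, kew = dh * (kh - 1) + 1, dw * (kw - 1) + 1

    def bwd(g):
        # g: [B, Co, Ho, Wo]
        if w.requires_grad:
            gw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))  # [Co, Ci, kh, kw]
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            Ho, Wo = g.shape[2], g.shape[3]
            # zero-stuff the output gradient by the stride
            gu = g
            if sh > 1 or sw > 1:
                gu = np.zeros((g.shape[0], g.shape[1], (Ho - 1) * sh + 1,
                               (Wo - 1) * sw + 1), dtype=DTYPE)
                gu[:, :, ::sh, ::sw] = g
            # full correlation with the spatially-flipped kernel
            plh = keh - 1 - ph
            plw = kew - 1 - pw
            prh = H + keh - 1 - plh - gu.shape[2]
            prw = W + kew - 1 - plw - gu.shape[3]
            gp = np.pad(gu, ((0, 0), (0, 0), (max(plh, 0), max(prh, 0)),
                             (max(plw, 0), max(prw, 0))))
            if plh < 0 or plw < 0 or prh < 0 or prw < 0:
                # negative pad = crop
                sl_h = slice(max(-plh, 0), gp.shape[2] - max(-prh, 0))
                sl_w = slice(max(-plw, 0), gp.shape[3] - max(-prw, 0))
                gp = gp[:, :, sl_h, sl_w]
            wf = w.data[:, :, ::-1, ::-1]
            wing = _conv_windows(gp, kh, kw, 1, 1, dh, dw)  # [B, Co, H, W, kh, kw]
            gx = np.tensordot(wing, wf, axes=([1, 4, 5], [0, 2, 3]))  # [B, H, W, Ci]
            x._accum(np.ascontiguousarray(gx.transpose(0, 3, 1, 2)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, bwd)


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int,
               eps: float = 1e-5) -> Tensor:
    """Group normalisation over [B, C, H, W] with per-channel affine."""
    B, C, H, W = x.data.shape
    g = groups
    xg = x.data.reshape(B, g, C // g * H * W)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(B, C, H, W)
    out_data = xhat * gamma.data.reshape(1, C, 1, 1) + beta.data.reshape(1, C, 1, 1)

    def bwd(go):
        if gamma.requires_grad:
            gamma._accum((go * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(go.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gh = (go * gamma.data.reshape(1, C, 1, 1)).reshape(B, g, -1)
            xh = xhat.reshape(B, g, -1)
            n = xh.shape[2]
            dx = (gh - gh.mean(axis=2, keepdims=True)
                  - xh * (gh * xh).mean(axis=2, keepdims=True)) * inv
            x._accum(dx.reshape(B, C, H, W).astype(DTYPE))

    return Tensor._make(out_data, (x, gamma, beta), bwd)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalisation over [B, C, H, W]; updates running stats in place."""
    B, C, H, W = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n = B * H * W
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv = (1.0 / np.sqrt(var + eps)).astype(DTYPE)
    xhat = (x.data - mu.reshape(1, C, 1, 1)) * inv.reshape(1, C, 1, 1)
    out_data = xhat * gamma.data.reshape(1, C, 1, 1) + beta.data.reshape(1, C, 1, 1)

    def bwd(go):
        if gamma.requires_grad:
            gamma._accum((go * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(go.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = gamma.data.reshape(1, C, 1, 1) * inv.reshape(1, C, 1, 1)
            if training:
                n = B * H * W
                gh = go * gamma.data.reshape(1, C, 1, 1)
                mean_gh = gh.mean(axis=(0, 2, 3), keepdims=True)
                mean_ghx = (gh * xhat).mean(axis=(0, 2, 3), keepdims=True)
                dx = (gh - mean_gh - xhat * mean_ghx) * inv.reshape(1, C, 1, 1)
                x._accum(dx.astype(DTYPE))
            else:
                x._accum(go * gi)

    return Tensor._make(out_data, (x, gamma, beta), bwd)


def bce_with_logits(z: Tensor, target: np.ndarray, reduction: str = "sum") -> Tensor:
    """Numerically stable binary cross-entropy on logits, summed."""
    t = _as_array(target)
    zd = z.data
    loss = np.maximum(zd, 0) - zd * t + np.log1p(np.exp(-np.abs(zd)))
    out_data = loss.sum() if reduction == "sum" else loss

    def bwd(g):
        gg = g if reduction != "sum" else g.reshape(())
        z._accum((sigmoid_np(zd) - t) * gg)

    return Tensor._make(np.asarray(out_data, dtype=DTYPE), (z,), bwd)


def softmax_cross_entropy(logits: Tensor, target_probs: np.ndarray,
                          weights: np.ndarray | None = None) -> Tensor:
    """Sum over rows of CE(softmax(logits_r), target_probs_r) * weights_r.

    logits: [M, K]; target_probs rows sum to 1 (e.g. the two-bin bracketing
    targets of distribution focal loss); weights: [M] or None.
    """
    t = _as_array(target_probs)
    zd = logits.data
    zmax = zd.max(axis=1, keepdims=True)
    ez = np.exp(zd - zmax)
    sez = ez.sum(axis=1, keepdims=True)
    logp = (zd - zmax) - np.log(sez)
    per_row = -(t * logp).sum(axis=1)
    w = np.ones(zd.shape[0], dtype=DTYPE) if weights is None else _as_array(weights)
    out_data = np.asarray((per_row * w).sum(), dtype=DTYPE)

    def bwd(g):
        p = ez / sez
        logits._accum((p - t) * (w * float(g))[:, None])

    return Tensor._make(out_data, (logits,), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    zmax = x.data.max(axis=axis, keepdims=True)
    ez = np.exp(x.data - zmax)
    out_data = ez / ez.sum(axis=axis, keepdims=True)

    def bwd(g):
        s = out_data
        x._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

    return Tensor._make(out_data, (x,), bwd)
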