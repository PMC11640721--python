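"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the segmentation network needs: broadcast
elementwise arithmetic, ReLU/sigmoid/softmax, 3x3 and 1x1 convolutions via
im2col, 2x2 max pooling and nearest-neighbour upsampling, channel
concatenation, reductions, and a fused softmax cross-entropy.  Gradients
are accumulated on a tape and released by topological backward traversal.

All arrays are float32; convolution inner products run through BLAS
(np.tensordot) so CPU training of small U-Nets stays tractable.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _backward: Optional[Callable[[np.ndarray], None]] = None,
                 _parents: tuple["Tensor", ...] = ()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward = _backward
        self._parents = _parents

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph utilities ----------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this node (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep U-Nets overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators ----------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _binary(a, b, out_data, da: Callable, db: Callable) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    req = a.requires_grad or b.requires_grad

    def backward(g: np.ndarray) -> None:
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(da(g), a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(db(g), b.data.shape))

    return Tensor(out_data, req, backward if req else None, (a, b))


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(a, b, a.data + b.data, lambda g: g, lambda g: g)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(a, b, a.data * b.data,
                   lambda g: g * b.data, lambda g: g * a.data)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(a, b, a.data / b.data,
                   lambda g: g / b.data,
                   lambda g: -g * a.data / (b.data * b.data))


def _unary(a: Tensor, out_data, da: Callable) -> Tensor:
    req = a.requires_grad or bool(a._parents)

    def backward(g: np.ndarray) -> None:
        a._accumulate(da(g))

    return Tensor(out_data, req, backward if req else None, (a,))


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    return _unary(a, a.data * mask, lambda g: g * mask)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    z = a.data
    s = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                 np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
    return _unary(a, s, lambda g: g * s * (1.0 - s))


def softmax(a, axis: int = 1) -> Tensor:
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)
    return _unary(a, p, lambda g: p * (g - (g * p).sum(axis=axis, keepdims=True)))


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def da(g: np.ndarray) -> np.ndarray:
        if axis is None:
            return np.broadcast_to(g, a.data.shape).astype(DTYPE)
        gg = g if keepdims else np.expand_dims(g, axis)
        return np.broadcast_to(gg, a.data.shape).astype(DTYPE)

    return _unary(a, out, da)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[i] for i in np.atleast_1d(axis)])
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad or t._parents for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray) -> None:
        for t, gp in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(gp)

    return Tensor(out, req, backward if req else None, tuple(tensors))


# -- spatial ops ------------------------------------------------------------


def conv2d(x, w, b=None, pad: int = 1) -> Tensor:
    """Cross-correlation of (N,C,H,W) with (O,C,kh,kw), stride 1."""
    x, w = _as_tensor(x), _as_tensor(w)
    parents = [x, w]
    N, C, H, W = x.data.shape
    O, C2, kh, kw = w.data.shape
    assert C == C2, f"channel mismatch {C} vs {C2}"
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    # view (N, C, Ho, Wo, kh, kw), zero copy
    cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    out = np.einsum("nchwij,ocij->nohw", cols, w.data, optimize=True)
    if b is not None:
        b = _as_tensor(b)
        parents.append(b)
        out += b.data.reshape(1, O, 1, 1)
    Ho, Wo = out.shape[2], out.shape[3]
    req = any(p.requires_grad or p._parents for p in parents)

    def backward(g: np.ndarray) -> None:
        # dW: correlate input windows with output gradient
        if w.requires_grad or w._parents:
            dw = np.einsum("nohw,nchwij->ocij", g, cols, optimize=True)
            w._accumulate(dw)
        if b is not None and (b.requires_grad or b._parents):
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    # g:(N,O,Ho,Wo) x w[:,:,i,j]:(O,C) -> (N,C,Ho,Wo)
                    dxp[:, :, i:i + Ho, j:j + Wo] += np.einsum(
                        "nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True)
            x._accumulate(dxp[:, :, pad:pad + H, pad:pad + W] if pad else dxp)

    return Tensor(out, req, backward if req else None, tuple(parents))


def maxpool2(x) -> Tensor:
    """2x2 max pooling, stride 2; gradient routed to the first argmax."""
    x = _as_tensor(x)
    N, C, H, W = x.data.shape
    assert H % 2 == 0 and W % 2 == 0, "maxpool2 needs even spatial dims"
    win = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(N, C, H // 2, W // 2, 4)
    arg = win.argmax(axis=-1)
    out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def backward(g: np.ndarray) -> None:
        dwin = np.zeros_like(win)
        np.put_along_axis(dwin, arg[..., None], g[..., None], axis=-1)
        dx = dwin.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(dx.reshape(N, C, H, W))

    req = x.requires_grad or bool(x._parents)
    return Tensor(out, req, backward if req else None, (x,))


def upsample2(x) -> Tensor:
    """Nearest-neighbour 2x upsampling; gradient sums 2x2 blocks."""
    x = _as_tensor(x)
    N, C, H, W = x.data.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g: np.ndarray) -> None:
        x._accumulate(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    req = x.requires_grad or bool(x._parents)
    return Tensor(out, req, backward if req else None, (x,))


# -- losses -----------------------------------------------------------------


def softmax_cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean pixelwise cross-entropy; ``target`` is an integer class map.

    Fused with softmax for numerical stability (gradient is (p - y)/n).
    """
    logits = _as_tensor(logits)
    N, K, H, W = logits.data.shape
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    t = np.asarray(target)
    onehot = np.moveaxis(np.eye(K, dtype=DTYPE)[t], -1, 1)
    n_pix = N * H * W
    loss = float(-(onehot * np.log(p + 1e-12)).sum() / n_pix)

    def backward(g: np.ndarray) -> None:
        logits._accumulate(g * (p - onehot) / n_pix)

    req = logits.requires_grad or bool(logits._parents)
    return Tensor(loss, req, backward if req else None, (logits,))


def soft_dice_loss(logits: Tensor, target: np.ndarray,
                   eps: float = 1.0) -> Tensor:
    """1 - mean soft Dice over classes, from softmax probabilities."""
    logits = _as_tensor(logits)
    K = logits.data.shape[1]
    p = softmax(logits, axis=1)
    onehot = np.moveaxis(np.eye(K, dtype=DTYPE)[np.asarray(target)], -1, 1)
    inter = tsum(mul(p, onehot), axis=(0, 2, 3))
    denom = add(tsum(p, axis=(0, 2, 3)), onehot.sum(axis=(0, 2, 3)))
    dice = div(add(mul(inter, 2.0), eps), add(denom, eps))
    return add(1.0, mul(tmean(dice), -1.0))


# -- parameters / optimiser -------------------------------------------------


def he_init(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int) -> Tensor:
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)
    return Tensor(w, requires_grad=True)


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mh = m / (1 - b1 ** self.t)
            vh = v / (1 - b2 ** self.t)
            p.data -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(DTYPE)
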