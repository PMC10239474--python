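"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine implements exactly the operations needed by the volumetric
Swin-Conv-UNet and its training objective: broadcasted arithmetic,
batched matrix products, shape manipulation, windowed attention helpers
and two specialised 3D convolution primitives.  Gradients propagate
through a topologically-sorted tape of closures.

Arrays keep the dtype they are given; the network trains in float32
while gradient checks can run the same graph in float64.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "softmax", "layernorm", "conv3d",
           "conv_down2", "conv_up2", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager that suspends graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- autograd machinery -------------------------------------------------
    def _accumulate(self, grad: np.ndarray, own: bool = False) -> None:
        if self.grad is None:
            if own and grad.dtype == self.data.dtype:
                self.grad = grad
            else:
                self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node.grad = None   # interior gradients are no longer needed

    # -- helpers ------------------------------------------------------------
    def _lift(self, x) -> "Tensor":
        """Wrap a constant; scalars follow this tensor's dtype to avoid
        silently upcasting a float32 graph to float64."""
        if isinstance(x, Tensor):
            return x
        arr = np.asarray(x)
        if arr.dtype != self.dtype and arr.dtype.kind in "fi":
            arr = arr.astype(self.dtype)
        return Tensor(arr)

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        return Tensor(data, req, parents if req else (), backward if req else None)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g):
            self._accumulate(-g, own=True)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape), own=True)
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape), own=True)

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        return self * other.power(-1.0)

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self.power(-1.0)

    def power(self, p: float) -> "Tensor":
        out = self.data ** p

        def bwd(g):
            self._accumulate(g * p * self.data ** (p - 1.0), own=True)

        return self._make(out, (self,), bwd)

    def exp(self) -> "Tensor":
        out = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out, own=True)

        return self._make(out, (self,), bwd)

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape), own=True)
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape), own=True)

        return self._make(np.matmul(self.data, other.data), (self, other), bwd)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, self.shape).astype(self.dtype),
                             own=True)

        return self._make(out, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation -------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def bwd(g):
            self._accumulate(g.reshape(orig))

        return self._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            self._accumulate(np.transpose(g, inv))

        return self._make(np.transpose(self.data, axes), (self,), bwd)

    def __getitem__(self, idx) -> "Tensor":
        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accumulate(full, own=True)

        return self._make(self.data[idx], (self,), bwd)

    def roll(self, shift: Sequence[int], axis: Sequence[int]) -> "Tensor":
        shift = tuple(shift)
        axis = tuple(axis)

        def bwd(g):
            self._accumulate(np.roll(g, tuple(-s for s in shift), axis))

        return self._make(np.roll(self.data, shift, axis), (self,), bwd)

    # -- activations --------------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g):
            self._accumulate(g * mask, own=True)

        return self._make(self.data * mask, (self,), bwd)

    def gelu(self) -> "Tensor":
        # tanh approximation; smooth and cheap
        c = math.sqrt(2.0 / math.pi)
        x = self.data
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out = 0.5 * x * (1.0 + t)

        def bwd(g):
            dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
            d = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * dinner
            self._accumulate(g * d, own=True)

        return self._make(out, (self,), bwd)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    req = _GRAD_ENABLED and any(t.requires_grad for t in tensors)
    return Tensor(out, req, tuple(tensors) if req else (), bwd if req else None)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot), own=True)

    return x._make(s, (x,), bwd)


def layernorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalisation over the last axis."""
    n = x.shape[-1]
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma.data + beta.data

    def bwd(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=tuple(range(g.ndim - 1))))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
        if x.requires_grad:
            gh = g * gamma.data
            m1 = gh.mean(axis=-1, keepdims=True)
            m2 = (gh * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(((gh - m1 - xhat * m2) * inv).astype(x.dtype),
                          own=True)

    return x._make(out, (x, gamma, beta), bwd)


# -- convolution primitives --------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B,C,D,H,W) -> (B, D*H*W, C*k^3) for stride-1 'same' convolution."""
    b, c, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    # win: (B, C, D, H, W, k, k, k) -> (B, D*H*W, C*k^3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
        b, d * h * w, c * k ** 3)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-size 3D convolution, odd kernel, stride 1.

    ``weight`` has shape (C_in, k, k, k, C_out); ``bias`` (C_out,).
    """
    cin, k = weight.shape[0], weight.shape[1]
    pad = k // 2
    b, c, d, h, w = x.shape
    if c != cin:
        raise ValueError(f"expected {cin} input channels, got {c}")
    cols = _im2col(x.data, k, pad)
    wmat = weight.data.reshape(cin * k ** 3, -1)
    out = cols @ wmat + bias.data
    cout = out.shape[-1]
    out = out.reshape(b, d, h, w, cout).transpose(0, 4, 1, 2, 3)
    del cols   # recomputed in backward; keeping it would dominate memory

    def bwd(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(
            b, d * h * w, cout)
        if bias.requires_grad:
            bias._accumulate(gmat.sum(axis=(0, 1)))
        if weight.requires_grad:
            gw = np.einsum("bnc,bno->co", _im2col(x.data, k, pad), gmat,
                           optimize=True)
            weight._accumulate(gw.reshape(weight.shape))
        if x.requires_grad:
            # full correlation of g with the spatially flipped kernel
            wflip = weight.data[:, ::-1, ::-1, ::-1, :]
            wback = np.ascontiguousarray(
                wflip.transpose(4, 1, 2, 3, 0)).reshape(cout * k ** 3, cin)
            gcols = _im2col(g, k, pad)
            gx = (gcols @ wback).reshape(b, d, h, w, cin).transpose(0, 4, 1, 2, 3)
            x._accumulate(np.ascontiguousarray(gx), own=True)

    return x._make(out, (x, weight, bias), bwd)


def conv_down2(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """3D convolution with kernel 2 and stride 2 (halves each spatial side).

    ``weight``: (C_in, 2, 2, 2, C_out).
    """
    b, c, d, h, w = x.shape
    blocks = x.data.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2)
    cols = np.ascontiguousarray(
        blocks.transpose(0, 2, 4, 6, 1, 3, 5, 7)).reshape(
        b, (d // 2) * (h // 2) * (w // 2), c * 8)
    wmat = weight.data.reshape(c * 8, -1)
    out = cols @ wmat + bias.data
    cout = out.shape[-1]
    out = out.reshape(b, d // 2, h // 2, w // 2, cout).transpose(0, 4, 1, 2, 3)

    def bwd(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(
            b, -1, cout)
        if bias.requires_grad:
            bias._accumulate(gmat.sum(axis=(0, 1)))
        if weight.requires_grad:
            gw = np.einsum("bnc,bno->co", cols, gmat, optimize=True)
            weight._accumulate(gw.reshape(weight.shape))
        if x.requires_grad:
            gcols = gmat @ wmat.T
            gx = gcols.reshape(b, d // 2, h // 2, w // 2, c, 2, 2, 2)
            gx = gx.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(b, c, d, h, w)
            x._accumulate(np.ascontiguousarray(gx), own=True)

    return x._make(out, (x, weight, bias), bwd)


def conv_up2(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """3D transposed convolution with kernel 2 and stride 2 (doubles sides).

    ``weight``: (C_in, 2, 2, 2, C_out).  Non-overlapping, so each input
    voxel paints one 2x2x2 output block.
    """
    b, c, d, h, w = x.shape
    cmat = np.ascontiguousarray(x.data.transpose(0, 2, 3, 4, 1)).reshape(
        b, d * h * w, c)
    wmat = weight.data.reshape(c, -1)  # (C_in, 8*C_out)
    cout = weight.shape[-1]
    out = cmat @ wmat  # (b, n, 8*C_out)
    out = out.reshape(b, d, h, w, 2, 2, 2, cout)
    out = out.transpose(0, 7, 1, 4, 2, 5, 3, 6).reshape(b, cout, 2 * d, 2 * h, 2 * w)
    out = out + bias.data[None, :, None, None, None]

    def bwd(g):
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3, 4)))
        gblk = g.reshape(b, cout, d, 2, h, 2, w, 2)
        gmat = np.ascontiguousarray(
            gblk.transpose(0, 2, 4, 6, 3, 5, 7, 1)).reshape(b, d * h * w, 8 * cout)
        if weight.requires_grad:
            gw = np.einsum("bnc,bno->co", cmat, gmat, optimize=True)
            weight._accumulate(gw.reshape(weight.shape))
        if x.requires_grad:
            gx = gmat @ wmat.T
            gx = gx.reshape(b, d, h, w, c).transpose(0, 4, 1, 2, 3)
            x._accumulate(np.ascontiguousarray(gx), own=True)

    return x._make(np.ascontiguousarray(out), (x, weight, bias), bwd)
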