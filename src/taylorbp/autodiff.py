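"""Minimal vectorized reverse-mode automatic differentiation.

A :class:`Tensor` wraps a ``numpy`` array and records the operations applied
to it; :meth:`Tensor.backward` runs one reverse sweep accumulating gradients
into every tensor created with ``requires_grad=True``.  The op set is exactly
what the blood-pressure network and its Taylor-consistency loss need:
elementwise arithmetic, matmul, 1-D convolution/max-pooling, ReLU/tanh,
reductions, indexing and concatenation.

The Taylor residual involves the network's gradient with respect to its
feature inputs.  Rather than nesting reverse passes, that gradient is written
in closed form out of these same primitives (see ``network.py``), so a single
reverse sweep differentiates the full physics loss with respect to the
weights.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "maxpool1d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = tuple(parents)

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- graph bookkeeping ----------------------------------------------------
    def _needs_graph(self, *others) -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad and self._backward is None:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        """Reverse sweep from this tensor; seeds with ones if scalar."""
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = bw
        return out

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        mask = self.data > 0
        out._backward = lambda g: self._accum(g * mask)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - t * t))
        return out

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accum(acc)

        out._backward = bw
        return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid (no padding), stride-1 cross-correlation.

    x: (B, C_in, L), w: (C_out, C_in, K), b: (C_out,) -> (B, C_out, L-K+1).
    """
    B, C_in, L = x.data.shape
    C_out, _, K = w.data.shape
    cols = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=2)  # B,Cin,Lo,K
    y = np.einsum("bclk,ock->bol", cols, w.data, optimize=True) + b.data[None, :, None]
    out = Tensor(y, parents=(x, w, b))

    def bw(g):
        w._accum(np.einsum("bol,bclk->ock", g, cols, optimize=True))
        b._accum(g.sum(axis=(0, 2)))
        # dx[b,c,t] = sum_{o,k} g[b,o,t-k] w[o,c,k]  (full correlation)
        gp = np.pad(g, ((0, 0), (0, 0), (K - 1, K - 1)))
        gw = np.lib.stride_tricks.sliding_window_view(gp, K, axis=2)  # B,Co,L,K
        x._accum(np.einsum("botk,ock->bct", gw, w.data[:, :, ::-1], optimize=True))

    out._backward = bw
    return out


def maxpool1d(x: Tensor, size: int, stride: int = 1) -> Tensor:
    """Max pooling over the last axis of (B, C, L)."""
    B, C, L = x.data.shape
    win = np.lib.stride_tricks.sliding_window_view(x.data, size, axis=2)
    win = win[:, :, ::stride]  # B, C, Lo, size
    arg = win.argmax(axis=3)
    out = Tensor(win.max(axis=3), parents=(x,))
    Lo = arg.shape[2]

    def bw(g):
        acc = np.zeros_like(x.data)
        bi, ci, li = np.meshgrid(
            np.arange(B), np.arange(C), np.arange(Lo), indexing="ij"
        )
        np.add.at(acc, (bi, ci, li * stride + arg), g)
        x._accum(acc)

    out._backward = bw
    return out
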