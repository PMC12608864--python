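"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The network in this package is small (per-point MLPs, single-head attention,
segment pooling), so a compact tape-based engine is sufficient: every
:class:`Tensor` records its parents and a backward closure, and
:meth:`Tensor.backward` runs a single reverse topological sweep.  All math is
float64 and single-threaded-deterministic; segment reductions used by the
slice encoder accumulate in a sorted order so that encoder outputs are
invariant to point permutation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads and tape references eagerly
                if not node.requires_grad:
                    node.grad = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * as_tensor(other).pow(-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * self.pow(-1.0)

    def pow(self, p: float):
        out = _node(np.power(self.data, p), (self,))

        def bw(g):
            self._accumulate(g * p * np.power(self.data, p - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _node(self.data @ other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(g @ other.data.T)
            if other.requires_grad or other._parents:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    # -- elementwise nonlinearities --------------------------------------
    def relu(self):
        mask = self.data > 0
        out = _node(np.where(mask, self.data, 0.0), (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = _node(y, (self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - y * y))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = _node(y, (self,))
        out._backward = lambda g: self._accumulate(g * y)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = _node(y, (self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / y)
        return out

    # -- reductions / shaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis, keepdims=False):
        y = self.data.max(axis=axis, keepdims=True)
        mask = self.data == y
        count = mask.sum(axis=axis, keepdims=True)
        out = _node(y if keepdims else np.squeeze(y, axis=axis), (self,))

        def bw(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            # gradient split equally among argmax ties (permutation symmetric)
            self._accumulate(mask * (g / count))

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    @property
    def T(self):
        out = _node(self.data.T, (self,))
        out._backward = lambda g: self._accumulate(g.T)
        return out

    def gather(self, idx):
        """Row gather y = x[idx]; duplicate indices accumulate on backward."""
        idx = np.asarray(idx, dtype=np.intp)
        out = _node(self.data[idx], (self,))

        def bw(g):
            dx = np.zeros_like(self.data)
            np.add.at(dx, idx, g)
            self._accumulate(dx)

        out._backward = bw
        return out

    def col(self, j):
        """Single-column slice as a 1-D tensor."""
        out = _node(self.data[:, j], (self,))

        def bw(g):
            dx = np.zeros_like(self.data)
            dx[:, j] = g
            self._accumulate(dx)

        out._backward = bw
        return out

    def rownorm(self):
        """Euclidean norm of each row of a 2-D tensor (exact at zero).

        The backward uses a guarded denominator, giving the zero subgradient
        at the origin.
        """
        y = np.sqrt((self.data * self.data).sum(axis=1))
        out = _node(y, (self,))

        def bw(g):
            denom = np.where(y > 0, y, 1.0)
            self._accumulate((g / denom)[:, None] * self.data)

        out._backward = bw
        return out

    # -- fused composite ops ----------------------------------------------
    def softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)
        out = _node(y, (self,))

        def bw(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accumulate(y * (g - dot))

        out._backward = bw
        return out

    def log_softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        y = shifted - lse
        out = _node(y, (self,))

        def bw(g):
            self._accumulate(g - np.exp(y) * g.sum(axis=axis, keepdims=True))

        out._backward = bw
        return out

    def layer_norm(self, gain: "Tensor", bias: "Tensor", eps: float = 1e-5):
        """Per-row normalization over the last axis with learnable affine."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = _node(xhat * gain.data + bias.data, (self, gain, bias))

        def bw(g):
            if gain.requires_grad or gain._parents:
                gain._accumulate(_unbroadcast(g * xhat, gain.data.shape))
            if bias.requires_grad or bias._parents:
                bias._accumulate(_unbroadcast(g, bias.data.shape))
            n = self.data.shape[-1]
            gx = g * gain.data
            self._accumulate(
                inv
                * (
                    gx
                    - gx.mean(axis=-1, keepdims=True)
                    - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
                )
            )

        out._backward = bw
        return out

    # -- segment ops (rows grouped by a sorted segment-id vector) ----------
    def segment_softmax(self, seg: np.ndarray, n_seg: int):
        """Softmax of a 1-D score vector within each segment.

        `seg` must be sorted ascending.  The normalizing sums accumulate in
        value-sorted order within each segment, so the result is bitwise
        invariant to permutation of rows inside a segment.
        """
        seg = np.asarray(seg, dtype=np.intp)
        x = self.data
        starts = np.searchsorted(seg, np.arange(n_seg))
        m = np.maximum.reduceat(x, starts) if len(x) else np.zeros(n_seg)
        e = np.exp(x - m[seg])
        order = np.lexsort((e, seg))
        denom = np.add.reduceat(e[order], np.searchsorted(seg[order], np.arange(n_seg)))
        y = e / denom[seg]
        out = _node(y, (self,))

        def bw(g):
            dot = np.zeros(n_seg)
            np.add.at(dot, seg, g * y)
            self._accumulate(y * (g - dot[seg]))

        out._backward = bw
        return out

    def segment_max(self, seg: np.ndarray, n_seg: int):
        """Columnwise max over rows of each segment (`seg` sorted ascending)."""
        seg = np.asarray(seg, dtype=np.intp)
        starts = np.searchsorted(seg, np.arange(n_seg))
        y = np.maximum.reduceat(self.data, starts, axis=0)
        mask = self.data == y[seg]
        count = np.zeros((n_seg, self.data.shape[1]))
        np.add.at(count, seg, mask)
        out = _node(y, (self,))

        def bw(g):
            self._accumulate(mask * (g[seg] / count[seg]))

        out._backward = bw
        return out

    def segment_sum(self, seg: np.ndarray, n_seg: int):
        """Row sums per segment id (seg need not be sorted)."""
        seg = np.asarray(seg, dtype=np.intp)
        y = np.zeros((n_seg,) + self.data.shape[1:])
        np.add.at(y, seg, self.data)
        out = _node(y, (self,))
        out._backward = lambda g: self._accumulate(g[seg])
        return out


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad or t._parents:
                t._accumulate(gpart)

    out._backward = bw
    return out
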