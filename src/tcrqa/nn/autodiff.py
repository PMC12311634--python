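"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough tape-based autodiff to train the geometric message-passing
regressor in this package: dense linears, channel-wise linear maps over
3-vector features, gather/segment-mean for message passing, elementwise
nonlinearities and reductions. Single precision throughout: the regressor
is small and the training signal is dominated by sampling noise, so the
memory-bandwidth savings win.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather", "segment_mean", "no_grad_data", "DTYPE"]

DTYPE = np.float32


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    # ---- graph mechanics ---------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad only on scalars")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=DTYPE)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        grad = _unbroadcast(np.asarray(grad, DTYPE), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    @property
    def shape(self):
        return self.data.shape

    def item(self):
        return float(self.data)

    # ---- ops ----------------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))
        out._backward = bw
        return out

    def __matmul__(self, other):
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        out._backward = bw
        return out

    def channel_linear(self, w: "Tensor"):
        """Linear map over the vector-channel axis: (n, v, 3), (h, v) -> (n, h, 3).

        Implemented as one large GEMM on a (v, n*3) view for throughput.
        """
        n, v, _ = self.data.shape
        h = w.data.shape[0]
        x_flat = self.data.transpose(1, 0, 2).reshape(v, n * 3)
        out_val = (w.data @ x_flat).reshape(h, n, 3).transpose(1, 0, 2)
        out = Tensor(out_val, parents=(self, w))

        def bw(g):
            g_flat = np.ascontiguousarray(g.transpose(1, 0, 2)).reshape(h, n * 3)
            if self.requires_grad:
                self._accum((w.data.T @ g_flat).reshape(v, n, 3).transpose(1, 0, 2))
            if w.requires_grad:
                w._accum(g_flat @ x_flat.T)
        out._backward = bw
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if self.requires_grad:
                gg = g
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)
        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))
        out._backward = bw
        return out

    def norm(self, axis=-1, keepdims=False, eps=1e-8):
        """Smooth L2 norm sqrt(sum x^2 + eps) along an axis."""
        sq = np.sum(self.data**2, axis=axis, keepdims=True) + eps
        nrm = np.sqrt(sq)
        val = nrm if keepdims else np.squeeze(nrm, axis=axis)
        out = Tensor(val, parents=(self,))

        def bw(g):
            if self.requires_grad:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(gg * self.data / nrm)
        out._backward = bw
        return out

    def dropout(self, p: float, rng: np.random.Generator, training: bool):
        if not training or p <= 0.0:
            return self
        mask = (rng.uniform(size=self.data.shape) >= p) / (1.0 - p)
        return self * Tensor(mask)


def _scatter_add(idx, n_rows, g):
    """Sum rows of ``g`` into ``n_rows`` bins given by ``idx`` (sparse matmul)."""
    from scipy import sparse

    flat = g.reshape(len(idx), -1)
    m = sparse.csr_matrix((np.ones(len(idx), DTYPE), (idx, np.arange(len(idx)))),
                          shape=(n_rows, len(idx)))
    return np.asarray(m @ flat).reshape((n_rows,) + g.shape[1:])


def concat(tensors, axis=-1):
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)
    out._backward = bw
    return out


def gather(x: Tensor, idx: np.ndarray):
    """Row gather x[idx] along the first axis."""
    idx = np.asarray(idx, np.int64)
    out = Tensor(x.data[idx], parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(_scatter_add(idx, x.data.shape[0], g))
    out._backward = bw
    return out


def segment_mean(x: Tensor, seg: np.ndarray, n_segments: int):
    """Mean of rows of x grouped by segment id (empty segments -> 0)."""
    seg = np.asarray(seg, np.int64)
    counts = np.bincount(seg, minlength=n_segments).astype(DTYPE)
    counts = np.maximum(counts, 1.0)
    acc = _scatter_add(seg, n_segments, x.data)
    cexp = counts.reshape((n_segments,) + (1,) * (x.data.ndim - 1))
    out = Tensor(acc / cexp, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum((g / cexp)[seg])
    out._backward = bw
    return out


def no_grad_data(t):
    return t.data if isinstance(t, Tensor) else np.asarray(t)
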