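"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape; :meth:`Tensor.backward` replays the tape in reverse topological
order and accumulates gradients.  The op set is exactly what the locus
encoders and the graph-attention trunk need: broadcasting arithmetic, matmul,
1-D convolution/pooling, row gather/scatter (for edge message passing),
reductions, concatenation and the usual pointwise nonlinearities.

All computation is float64 for reproducibility of the seeded-training
contract; speed-critical inner products go through BLAS via ``matmul``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_rows", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference passes)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- tape machinery -------------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        return self._make(self.data / other.data, (self, other), bwd)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bwd)

    def __pow__(self, p: float):
        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bwd)

    # -- pointwise ------------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bwd)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        factor = np.where(mask, 1.0, slope)

        def bwd(g):
            self._accum(g * factor)

        return self._make(self.data * factor, (self,), bwd)

    def elu(self, alpha: float = 1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(self.data > 0, self.data, neg)

        def bwd(g):
            self._accum(g * np.where(self.data > 0, 1.0, neg + alpha))

        return self._make(out_data, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), bwd)

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def bwd(g):
            self._accum(g.reshape(self.data.shape))

        return self._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        axes = axes or None
        inv = np.argsort(axes) if axes else None

        def bwd(g):
            self._accum(g.transpose(inv) if inv is not None else g.T)

        return self._make(self.data.transpose(axes), (self,), bwd)

    @property
    def T(self):
        return self.transpose()

    # -- gather / scatter (graph message passing) -----------------------------
    def take_rows(self, idx: np.ndarray):
        """Gather rows (axis 0); gradient scatter-adds back."""
        idx = np.asarray(idx, dtype=np.intp)

        def bwd(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accum(acc)

        return self._make(self.data[idx], (self,), bwd)

    def scatter_sum(self, idx: np.ndarray, n_out: int):
        """out[idx[i]] += self[i] (segment sum along axis 0)."""
        idx = np.asarray(idx, dtype=np.intp)
        out_data = np.zeros((n_out,) + self.data.shape[1:], dtype=np.float64)
        np.add.at(out_data, idx, self.data)

        def bwd(g):
            self._accum(g[idx])

        return self._make(out_data, (self,), bwd)

    # -- convolution / pooling (NCL layout) -----------------------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor", pad: int):
        """Cross-correlation: x (B,C,L), weight (O,C,K), bias (O,) -> (B,O,L').

        Implemented as im2col + BLAS matmul; L' = L + 2*pad - K + 1.
        """
        x, w = self.data, weight.data
        B, C, L = x.shape
        O, _, K = w.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        Lp = xp.shape[2]
        Lo = Lp - K + 1
        cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # B,C,Lo,K
        cols2 = cols.transpose(0, 2, 1, 3).reshape(B * Lo, C * K)
        wmat = w.reshape(O, C * K)
        out_data = (cols2 @ wmat.T).reshape(B, Lo, O).transpose(0, 2, 1)
        out_data = out_data + bias.data[None, :, None]

        def bwd(g):
            gmat = g.transpose(0, 2, 1).reshape(B * Lo, O)  # B*Lo, O
            if weight.requires_grad:
                weight._accum((gmat.T @ cols2).reshape(O, C, K))
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2)))
            if self.requires_grad:
                gcols = (gmat @ wmat).reshape(B, Lo, C, K).transpose(0, 2, 1, 3)
                gxp = np.zeros_like(xp)
                for k in range(K):
                    gxp[:, :, k : k + Lo] += gcols[:, :, :, k]
                self._accum(gxp[:, :, pad : pad + L] if pad else gxp)

        return self._make(out_data, (self, weight, bias), bwd)

    def amax(self, axis: int):
        """Max-reduce along one axis (ties: first index gets the gradient)."""
        arg = self.data.argmax(axis=axis)
        out_data = np.take_along_axis(self.data,
                                      np.expand_dims(arg, axis), axis)

        def bwd(g):
            acc = np.zeros_like(self.data)
            np.put_along_axis(acc, np.expand_dims(arg, axis),
                              np.expand_dims(g, axis), axis)
            self._accum(acc)

        return self._make(out_data.squeeze(axis), (self,), bwd)

    def max_pool1d(self, k: int):
        """Non-overlapping max pool along the last axis; length must divide k."""
        B, C, L = self.data.shape
        assert L % k == 0, "pool length must divide sequence length"
        resh = self.data.reshape(B, C, L // k, k)
        arg = resh.argmax(axis=3)
        out_data = np.take_along_axis(resh, arg[..., None], axis=3)[..., 0]

        def bwd(g):
            gr = np.zeros_like(resh)
            np.put_along_axis(gr, arg[..., None], g[..., None], axis=3)
            self._accum(gr.reshape(B, C, L))

        return self._make(out_data, (self,), bwd)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(out_data)
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                t._accum(piece)

        out._backward = bwd
    return out


def stack_rows(tensors: list[Tensor]) -> Tensor:
    """Stack 1-D tensors into a 2-D tensor (rows)."""
    out_data = np.stack([t.data for t in tensors], axis=0)
    out = Tensor(out_data)
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)

        def bwd(g):
            for i, t in enumerate(tensors):
                t._accum(g[i])

        out._backward = bwd
    return out
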