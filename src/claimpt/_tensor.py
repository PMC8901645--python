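"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical core the encoder and training loops are built on.
It implements exactly the operations the model needs — broadcasting
arithmetic, (batched) matmul, reductions, gathers, fused softmax /
cross-entropy primitives — with vector-Jacobian products, and nothing else.
Arrays keep whatever dtype they are given; model code uses float32,
gradient-check tests use float64.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "embedding", "softmax", "softmax_xent", "sigmoid_bce"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _vjp: Optional[Callable] = None,
    ):
        self.data = np.asarray(data)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad: Optional[np.ndarray] = None
        self._parents = tuple(_parents)
        self._vjp = _vjp

    # -- graph -------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: sequences can be deep
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._vjp(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(parent.data.dtype, copy=True)
                else:
                    parent.grad += g

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data
        return Tensor(
            out_data,
            _parents=(self, other),
            _vjp=lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _vjp=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        return Tensor(
            self.data * other.data,
            _parents=(self, other),
            _vjp=lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __pow__(self, n: float):
        if not np.isscalar(n):
            raise TypeError("only scalar exponents are supported")
        out = self.data ** n
        return Tensor(
            out, _parents=(self,), _vjp=lambda g: (g * n * self.data ** (n - 1),)
        )

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data

        def vjp(g):
            if b.ndim == 1:
                ga = np.expand_dims(g, -1) * b
                gb = _unbroadcast(np.expand_dims(a, -2).swapaxes(-1, -2) @ np.expand_dims(g, -1), b.shape + (1,))[..., 0]
            elif a.ndim == 1:
                ga = (g @ b.swapaxes(-1, -2)).reshape(a.shape)
                gb = _unbroadcast(np.outer(a, g), b.shape)
            else:
                ga = _unbroadcast(g @ b.swapaxes(-1, -2), a.shape)
                gb = _unbroadcast(a.swapaxes(-1, -2) @ g, b.shape)
            return ga, gb

        return Tensor(a @ b, _parents=(self, other), _vjp=vjp)

    def __getitem__(self, key):
        keys = key if isinstance(key, tuple) else (key,)
        fancy = any(isinstance(k, (np.ndarray, list)) for k in keys)

        def vjp(g):
            out = np.zeros_like(self.data)
            if fancy:
                np.add.at(out, key, g)  # accumulate repeated indices
            else:
                out[key] += g
            return (out,)

        return Tensor(self.data[key], _parents=(self,), _vjp=vjp)

    # -- elementwise -------------------------------------------------------

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, _parents=(self,), _vjp=lambda g: (g * out,))

    def log(self):
        return Tensor(
            np.log(self.data), _parents=(self,), _vjp=lambda g: (g / self.data,)
        )

    def relu(self):
        mask = self.data > 0
        return Tensor(
            self.data * mask, _parents=(self,), _vjp=lambda g: (g * mask,)
        )

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return Tensor(out, _parents=(self,), _vjp=vjp)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        out = self.data.max(axis=axis, keepdims=keepdims)

        def vjp(g):
            out_k = out if keepdims else np.expand_dims(out, axis)
            mask = self.data == out_k
            mask = mask / mask.sum(axis=axis, keepdims=True)  # split ties evenly
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (mask * g2,)

        return Tensor(out, _parents=(self,), _vjp=vjp)

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape):
        return Tensor(
            self.data.reshape(*shape),
            _parents=(self,),
            _vjp=lambda g: (g.reshape(self.shape),),
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(*axes),
            _parents=(self,),
            _vjp=lambda g: (g.transpose(*inv),),
        )


# -- free functions ---------------------------------------------------------


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; gradient splits evenly across ties."""
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    out = np.maximum(a.data, b.data)

    def vjp(g):
        ga = (a.data == out).astype(g.dtype)
        gb = (b.data == out).astype(g.dtype)
        denom = ga + gb
        return (
            _unbroadcast(g * ga / denom, a.shape),
            _unbroadcast(g * gb / denom, b.shape),
        )

    return Tensor(out, _parents=(a, b), _vjp=vjp)


def segment_max(rows: Tensor, seg_ids: np.ndarray, n_segments: int, fill: float = -1e9) -> Tensor:
    """Per-segment columnwise max of (N, d) rows → (n_segments, d).

    ``seg_ids`` must be sorted ascending; empty segments yield ``fill``.
    Gradient splits evenly across within-segment ties.
    """
    seg_ids = np.asarray(seg_ids)
    data = rows.data
    out = np.full((n_segments, data.shape[1]), fill, dtype=data.dtype)
    present, starts = np.unique(seg_ids, return_index=True)
    if len(present):
        out[present] = np.maximum.reduceat(data, starts, axis=0)

    def vjp(g):
        eq = (data == out[seg_ids]).astype(g.dtype)
        counts = np.add.reduceat(eq, starts, axis=0) if len(present) else eq
        full_counts = np.ones_like(out)
        full_counts[present] = counts
        return (eq / full_counts[seg_ids] * g[seg_ids],)

    return Tensor(out, _parents=(rows,), _vjp=vjp)


def scatter_rows(values: Tensor, index: tuple, shape: tuple) -> Tensor:
    """Place (M, d) rows at positions ``index`` (tuple of index arrays) of a
    zeros array of ``shape + (d,)``; the inverse gather is the gradient."""

    def vjp(g):
        return (g[index],)

    out = np.zeros(tuple(shape) + (values.shape[-1],), dtype=values.data.dtype)
    out[index] = values.data
    return Tensor(out, _parents=(values,), _vjp=vjp)


def layernorm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalisation over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gain.data + bias.data
    d = x.data.shape[-1]

    def vjp(g):
        gx_hat = g * gain.data
        gx = inv * (
            gx_hat
            - gx_hat.mean(axis=-1, keepdims=True)
            - xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True)
        )
        reduce_axes = tuple(range(g.ndim - 1))
        return (
            gx,
            (g * xhat).sum(axis=reduce_axes),
            g.sum(axis=reduce_axes),
        )

    return Tensor(out, _parents=(x, gain, bias), _vjp=vjp)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _vjp=vjp,
    )


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather: returns weight[idx] with scatter-add gradient."""
    idx = np.asarray(idx)

    def vjp(g):
        out = np.zeros_like(weight.data)
        np.add.at(out, idx, g)
        return (out,)

    return Tensor(weight.data[idx], _parents=(weight,), _vjp=vjp)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        return (s * (g - (g * s).sum(axis=axis, keepdims=True)),)

    return Tensor(s, _parents=(x,), _vjp=vjp)


def softmax_xent(logits: Tensor, target_probs: np.ndarray) -> Tensor:
    """Per-row cross-entropy −Σ_c w_c log softmax(logits)_c over the last axis.

    `target_probs` rows are non-negative weights (summing to 1 for a proper
    distribution); returns one loss value per leading index.
    """
    t = np.asarray(target_probs)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    loss = -(t * logp).sum(axis=-1)
    s = np.exp(logp)

    def vjp(g):
        return ((s - t) * np.expand_dims(g, -1),)

    return Tensor(loss, _parents=(logits,), _vjp=vjp)


def sigmoid_bce(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy with logits, numerically stable."""
    x, t = logits.data, np.asarray(targets)
    loss = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
    sig = 1.0 / (1.0 + np.exp(-x))

    def vjp(g):
        return (g * (sig - t),)

    return Tensor(loss, _parents=(logits,), _vjp=vjp)
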