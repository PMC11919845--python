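"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core of the package: a small, vectorised tape-based
autodiff engine providing exactly the primitives the drug/target encoders
need (dense linear algebra, elementwise nonlinearities, gather/scatter for
message passing on graphs, segment reductions for per-graph readout).

Design notes
------------
* ``Tensor`` wraps a ``float64`` ndarray.  Operations build a DAG; calling
  ``backward()`` on a scalar output runs reverse-mode accumulation over a
  topological ordering of that DAG.
* Gradients are accumulated on every tensor reached by the sweep (not only
  leaves) so intermediate feature maps can be interrogated, which the
  gradient-weighted attribution needs.
* Broadcasting in ``+``/``*`` is supported; the backward pass un-broadcasts
  by summing over the broadcast axes.
* ``segment_sum``/``segment_max`` reduce rows by integer segment id, which is
  how batched graphs (concatenated node matrices with an ownership vector)
  are pooled.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "gather",
    "segment_sum",
    "segment_max",
    "relu",
    "leaky_relu",
    "sigmoid",
    "tanh",
    "exp",
    "log",
    "sqrt",
    "clip_min",
    "Adam",
]


def _scatter_add_rows(out: np.ndarray, idx: np.ndarray, g: np.ndarray) -> None:
    """``out[idx] += g`` with repeated indices, via sort + reduceat
    (much faster than ``np.ufunc.at`` for large index arrays)."""
    if idx.size == 0:
        return
    if g.ndim == 1:
        out += np.bincount(idx, weights=g, minlength=out.shape[0])
        return
    order = np.argsort(idx, kind="stable")
    idx_s = idx[order]
    starts = np.concatenate(([0], np.flatnonzero(np.diff(idx_s)) + 1))
    out[idx_s[starts]] += np.add.reduceat(g[order], starts, axis=0)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None,
                 name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward
        self.name = name

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        # stored by reference: all accumulation is out-of-place, so shared
        # gradient arrays are never mutated
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float64)
        else:
            self.grad = self.grad + g

    def backward(self, grad=None):
        """Reverse-mode sweep from this tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: molecule graphs give deep tapes
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

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(_unbroadcast(-g * self.data / other.data ** 2, other.data.shape))
        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)
        out._backward = bw
        return out

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _parents=(self,))
        basic = isinstance(key, (int, slice)) or (
            isinstance(key, tuple) and all(isinstance(k, (int, slice)) for k in key))

        def bw(g):
            full = np.zeros_like(self.data)
            if basic:          # no repeated positions: direct add
                full[key] += g
            else:
                np.add.at(full, key, g)
            self._accumulate(full)
        out._backward = bw
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims=False):
        """Max reduction; ties send the gradient to the first maximiser."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor(out_data, _parents=(self,))

        def bw(g):
            if axis is None:
                mask = np.zeros_like(self.data)
                mask[np.unravel_index(np.argmax(self.data), self.data.shape)] = 1.0
                self._accumulate(mask * g)
                return
            idx = np.argmax(self.data, axis=axis)
            full = np.zeros_like(self.data)
            gg = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(full, np.expand_dims(idx, axis), gg, axis=axis)
            self._accumulate(full)
        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- functional primitives ------------------------------------------------

def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])
    out._backward = bw
    return out


def gather(t: Tensor, idx) -> Tensor:
    """Row gather ``t[idx]`` for an integer index array of any shape."""
    idx = np.asarray(idx, dtype=np.intp)
    flat = idx.reshape(-1)
    out = Tensor(t.data[idx], _parents=(t,))

    def bw(g):
        full = np.zeros_like(t.data)
        _scatter_add_rows(full, flat, g.reshape((flat.size,) + t.data.shape[1:]))
        t._accumulate(full)
    out._backward = bw
    return out


def segment_sum(t: Tensor, segment_ids, num_segments: int) -> Tensor:
    """Sum rows of ``t`` by segment id: ``out[s] = sum_{i: seg[i]==s} t[i]``."""
    seg = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.zeros((num_segments,) + t.data.shape[1:], dtype=np.float64)
    _scatter_add_rows(out_data, seg, t.data)
    out = Tensor(out_data, _parents=(t,))
    out._backward = lambda g: t._accumulate(g[seg])
    return out


def segment_max(t: Tensor, segment_ids, num_segments: int) -> Tensor:
    """Per-segment row-wise max; empty segments yield -inf (caller's contract)."""
    seg = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.full((num_segments,) + t.data.shape[1:], -np.inf)
    np.maximum.at(out_data, seg, t.data)
    out = Tensor(out_data, _parents=(t,))
    # route gradient to the first row attaining the per-segment max
    is_max = t.data == out_data[seg]
    first = np.zeros_like(is_max)
    claimed = np.zeros_like(out_data, dtype=bool)
    for i in np.argsort(seg, kind="stable"):
        pick = is_max[i] & ~claimed[seg[i]]
        first[i] = pick
        claimed[seg[i]] |= pick

    def bw(g):
        t._accumulate(np.where(first, g[seg], 0.0))
    out._backward = bw
    return out


def relu(t: Tensor) -> Tensor:
    out = Tensor(np.maximum(t.data, 0.0), _parents=(t,))
    out._backward = lambda g: t._accumulate(g * (t.data > 0))
    return out


def leaky_relu(t: Tensor, slope: float = 0.2) -> Tensor:
    out = Tensor(np.where(t.data > 0, t.data, slope * t.data), _parents=(t,))
    out._backward = lambda g: t._accumulate(g * np.where(t.data > 0, 1.0, slope))
    return out


def sigmoid(t: Tensor) -> Tensor:
    s = expit(t.data)
    out = Tensor(s, _parents=(t,))
    out._backward = lambda g: t._accumulate(g * s * (1.0 - s))
    return out


def tanh(t: Tensor) -> Tensor:
    y = np.tanh(t.data)
    out = Tensor(y, _parents=(t,))
    out._backward = lambda g: t._accumulate(g * (1.0 - y ** 2))
    return out


def exp(t: Tensor) -> Tensor:
    y = np.exp(t.data)
    out = Tensor(y, _parents=(t,))
    out._backward = lambda g: t._accumulate(g * y)
    return out


def log(t: Tensor) -> Tensor:
    out = Tensor(np.log(t.data), _parents=(t,))
    out._backward = lambda g: t._accumulate(g / t.data)
    return out


def sqrt(t: Tensor) -> Tensor:
    y = np.sqrt(t.data)
    out = Tensor(y, _parents=(t,))
    out._backward = lambda g: t._accumulate(g * 0.5 / y)
    return out


def clip_min(t: Tensor, lo: float) -> Tensor:
    """max(t, lo); gradient passes only where t > lo."""
    out = Tensor(np.maximum(t.data, lo), _parents=(t,))
    out._backward = lambda g: t._accumulate(g * (t.data > lo))
    return out


class Adam:
    """Adam optimiser over a flat dict of parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
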