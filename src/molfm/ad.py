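"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The denoiser is a small SE(3)-equivariant graph network; everything it needs
is a handful of dense ops (linear maps, pointwise nonlinearities, segment
aggregation over graph edges, vector norms and cross products). This module
provides exactly those ops on a :class:`Tensor` that records a tape and
replays it backwards. All arithmetic is float64.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`.
Ops executed inside :func:`no_grad` build no tape.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling tape construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array plus an optional autodiff tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction of intermediate nodes ---------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                if node.grad is None:
                    node.grad = g.copy()
                else:
                    node.grad = node.grad + g
            else:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, power(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data + b.data

    def backward(g):
        return ((a, _unbroadcast(g, a.data.shape)),
                (b, _unbroadcast(g, b.data.shape)))

    return Tensor._make(out, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data * b.data

    def backward(g):
        return ((a, _unbroadcast(g * b.data, a.data.shape)),
                (b, _unbroadcast(g * a.data, b.data.shape)))

    return Tensor._make(out, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    out = a.data ** exponent

    def backward(g):
        return ((a, g * exponent * a.data ** (exponent - 1.0)),)

    return Tensor._make(out, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data @ b.data

    def backward(g):
        return ((a, g @ b.data.T), (b, a.data.T @ g))

    return Tensor._make(out, (a, b), backward)


def linear(x, W, b) -> Tensor:
    """Fused affine map ``x @ W + b`` (one tape node instead of two)."""
    x, W, b = _as_tensor(x), _as_tensor(W), _as_tensor(b)
    out = x.data @ W.data + b.data

    def backward(g):
        return ((x, g @ W.data.T), (W, x.data.T @ g), (b, g.sum(axis=0)))

    return Tensor._make(out, (x, W, b), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out = np.exp(a.data)

    def backward(g):
        return ((a, g * out),)

    return Tensor._make(out, (a,), backward)


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    out = np.tanh(a.data)

    def backward(g):
        return ((a, g * (1.0 - out * out)),)

    return Tensor._make(out, (a,), backward)


def sigmoid(a) -> Tensor:
    from scipy.special import expit
    a = _as_tensor(a)
    out = expit(a.data)

    def backward(g):
        return ((a, g * out * (1.0 - out)),)

    return Tensor._make(out, (a,), backward)


def silu(a) -> Tensor:
    from scipy.special import expit
    a = _as_tensor(a)
    s = expit(a.data)
    out = a.data * s

    def backward(g):
        return ((a, g * (s * (1.0 + a.data * (1.0 - s)))),)

    return Tensor._make(out, (a,), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis=axis)
        return ((a, np.broadcast_to(g, a.data.shape).copy()),)

    return Tensor._make(out, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    out = a.data.reshape(shape)

    def backward(g):
        return ((a, g.reshape(a.data.shape)),)

    return Tensor._make(out, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = _as_tensor(a)
    out = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        return ((a, full),)

    return Tensor._make(out, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]

    def backward(g):
        pieces = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        return tuple(zip(ts, pieces))

    return Tensor._make(out, ts, backward)


def gather(a, index: np.ndarray) -> Tensor:
    """Row gather along axis 0 (``a[index]`` with integer index array)."""
    a = _as_tensor(a)
    index = np.asarray(index, dtype=np.int64)
    out = a.data[index]

    def backward(g):
        return ((a, _scatter_sum(g, index, a.data.shape[0])),)

    return Tensor._make(out, (a,), backward)


def _scatter_sum(data: np.ndarray, ids: np.ndarray, n: int) -> np.ndarray:
    """Sum rows into ``n`` buckets; uses reduceat when ids are sorted."""
    out = np.zeros((n,) + data.shape[1:], dtype=np.float64)
    if len(ids) == 0:
        return out
    if np.all(ids[1:] >= ids[:-1]):  # sorted: contiguous-run reduction
        starts = np.flatnonzero(np.r_[True, ids[1:] > ids[:-1]])
        out[ids[starts]] = np.add.reduceat(data, starts, axis=0)
    else:
        np.add.at(out, ids, data)
    return out


def segment_sum(a, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``num_segments`` buckets along axis 0."""
    a = _as_tensor(a)
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    out = _scatter_sum(a.data, segment_ids, num_segments)

    def backward(g):
        return ((a, g[segment_ids]),)

    return Tensor._make(out, (a,), backward)


def segment_mean(a, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Mean of rows per segment; empty segments yield zero rows."""
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    counts = np.bincount(segment_ids, minlength=num_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    summed = segment_sum(a, segment_ids, num_segments)
    inv = (1.0 / counts).reshape((num_segments,) + (1,) * (summed.ndim - 1))
    return mul(summed, inv)


def vec_linear(W, V) -> Tensor:
    """Channel-mixing linear map on vector features.

    ``W``: (out_channels, in_channels); ``V``: (N, in_channels, 3).
    Acts per node on the channel axis only, hence rotation-equivariant.
    """
    W, V = _as_tensor(W), _as_tensor(V)
    out = np.matmul(W.data[None], V.data)  # (1,h,c) @ (N,c,3) -> (N,h,3)

    def backward(g):
        gW = np.tensordot(g, V.data, axes=([0, 2], [0, 2]))
        gV = np.matmul(W.data.T[None], g)
        return ((W, gW), (V, gV))

    return Tensor._make(out, (W, V), backward)


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross product over the last axis (size 3), avoiding np.cross overhead."""
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    a0, a1, a2 = a[..., 0], a[..., 1], a[..., 2]
    b0, b1, b2 = b[..., 0], b[..., 1], b[..., 2]
    out[..., 0] = a1 * b2 - a2 * b1
    out[..., 1] = a2 * b0 - a0 * b2
    out[..., 2] = a0 * b1 - a1 * b0
    return out


def cross(a, b) -> Tensor:
    """Cross product along the last axis (size 3)."""
    a, b = _as_tensor(a), _as_tensor(b)
    out = _cross3(a.data, b.data)

    def backward(g):
        # (δa × b)·g = δa·(b × g);  (a × δb)·g = δb·(g × a)
        return ((a, _cross3(b.data, g)), (b, _cross3(g, a.data)))

    return Tensor._make(out, (a, b), backward)


def vnorm(a, eps: float = 1e-8) -> Tensor:
    """Euclidean norm along the last axis, smoothed at zero by ``eps``."""
    a = _as_tensor(a)
    sq = np.sum(a.data * a.data, axis=-1)
    out = np.sqrt(sq + eps)

    def backward(g):
        return ((a, (g / out)[..., None] * a.data),)

    return Tensor._make(out, (a,), backward)


def dot_last(a, b) -> Tensor:
    """Inner product along the last axis."""
    a, b = _as_tensor(a), _as_tensor(b)
    out = np.sum(a.data * b.data, axis=-1)

    def backward(g):
        return ((a, g[..., None] * b.data), (b, g[..., None] * a.data))

    return Tensor._make(out, (a, b), backward)


def layer_norm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = gamma.data * xhat + beta.data

    def backward(g):
        D = x.data.shape[-1]
        ggam = _unbroadcast(g * xhat, gamma.data.shape)
        gbet = _unbroadcast(g, beta.data.shape)
        gx_hat = g * gamma.data
        gx = inv / D * (D * gx_hat
                        - gx_hat.sum(axis=-1, keepdims=True)
                        - xhat * (gx_hat * xhat).sum(axis=-1, keepdims=True))
        return ((x, gx), (gamma, ggam), (beta, gbet))

    return Tensor._make(out, (x, gamma, beta), backward)


def log_softmax(logits) -> Tensor:
    logits = _as_tensor(logits)
    m = logits.data.max(axis=-1, keepdims=True)
    z = logits.data - m
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    out = z - lse

    def backward(g):
        p = np.exp(out)
        return ((logits, g - p * g.sum(axis=-1, keepdims=True)),)

    return Tensor._make(out, (logits,), backward)


def masked_cross_entropy(logits, targets: np.ndarray,
                         mask: np.ndarray | None = None) -> Tensor:
    """Mean cross-entropy of ``targets`` under softmax(logits).

    ``mask`` selects which rows contribute; the mean runs over selected rows
    only. With zero selected rows the result is exactly 0 (no gradient).
    """
    logits = _as_tensor(logits)
    targets = np.asarray(targets, dtype=np.int64)
    n = logits.data.shape[0]
    w = np.ones(n) if mask is None else np.asarray(mask, dtype=np.float64)
    denom = w.sum()
    if denom == 0:
        return Tensor(0.0)
    lsm = log_softmax(logits)
    picked = gather_cols(lsm, targets)
    return mul(tsum(mul(picked, -w / denom)), 1.0)


def gather_cols(a, cols: np.ndarray) -> Tensor:
    """Pick one column per row: out[i] = a[i, cols[i]]."""
    a = _as_tensor(a)
    cols = np.asarray(cols, dtype=np.int64)
    rows = np.arange(a.data.shape[0])
    out = a.data[rows, cols]

    def backward(g):
        full = np.zeros_like(a.data)
        full[rows, cols] = g
        return ((a, full),)

    return Tensor._make(out, (a,), backward)


def to_numpy(x) -> np.ndarray:
    """Unwrap a Tensor (or pass through an array-like) as a NumPy array."""
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def softmax_np(logits: np.ndarray) -> np.ndarray:
    """Plain-NumPy softmax over the last axis (no tape)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# parameter containers & optimizer
# ---------------------------------------------------------------------------

class Module:
    """Base class with recursive named-parameter collection."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        self._collect("", out)
        return out

    def _collect(self, prefix: str, out: dict[str, Tensor]) -> None:
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                out[key] = val
            elif isinstance(val, Module):
                val._collect(key + ".", out)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        item._collect(f"{key}.{i}.", out)
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{key}.{i}"] = item

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:5]}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters().values())


class Adam:
    """Adam optimizer over a named-parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            p.data -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": {k: v.copy() for k, v in self.m.items()},
                "v": {k: v.copy() for k, v in self.v.items()}}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = {k: np.asarray(v, dtype=np.float64) for k, v in state["m"].items()}
        self.v = {k: np.asarray(v, dtype=np.float64) for k, v in state["v"].items()}
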