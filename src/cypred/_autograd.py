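"""Compact reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operations the ring-aware graph encoder needs: dense
and sparse matrix products, row gathering, concatenation, elementwise
arithmetic, ReLU, row normalization, segment pooling via sparse operators,
mean-squared-error and softmax-cross-entropy heads, plus an Adam optimizer.
Gradients are checked against central differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> np.ndarray:
        return self.data

    # -- graph traversal ----------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient only on scalars")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad = self.grad + g


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# primitive ops


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    out._backward = bw
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    return add(a, scale(b, -1.0))


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    out._backward = bw
    return out


def scale(a: Tensor, c: float) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data * c, parents=(a,))

    def bw(g):
        if a.requires_grad:
            a._accum(g * c)

    out._backward = bw
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    out._backward = bw
    return out


def matmul_t(a: Tensor, b: Tensor) -> Tensor:
    """a @ b.T with gradient flowing to both operands (may be the same node)."""
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data @ b.data.T, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accum(g @ b.data)
        if b.requires_grad:
            b._accum(g.T @ a.data)

    out._backward = bw
    return out


def spmm(sp_mat: sparse.spmatrix, x: Tensor) -> Tensor:
    """Sparse @ dense; the sparse operator is a constant (graph structure)."""
    x = _wrap(x)
    sp_mat = sparse.csr_matrix(sp_mat)
    out = Tensor(sp_mat @ x.data, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(sp_mat.T @ g)

    out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accum(np.take(g, range(lo, hi), axis=axis))

    out._backward = bw
    return out


def relu(a: Tensor) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    out = Tensor(a.data * mask, parents=(a,))

    def bw(g):
        if a.requires_grad:
            a._accum(g * mask)

    out._backward = bw
    return out


def gather_rows(a: Tensor, idx) -> Tensor:
    a = _wrap(a)
    idx = np.asarray(idx, dtype=int)
    out = Tensor(a.data[idx], parents=(a,))

    def bw(g):
        if a.requires_grad:
            acc = np.zeros_like(a.data)
            np.add.at(acc, idx, g)
            a._accum(acc)

    out._backward = bw
    return out


def rownorm(a: Tensor, eps: float = 1e-12) -> Tensor:
    """L2-normalize each row."""
    a = _wrap(a)
    norms = np.linalg.norm(a.data, axis=1, keepdims=True)
    norms = np.maximum(norms, eps)
    y = a.data / norms
    out = Tensor(y, parents=(a,))

    def bw(g):
        if a.requires_grad:
            dot = np.sum(g * y, axis=1, keepdims=True)
            a._accum((g - y * dot) / norms)

    out._backward = bw
    return out


def mse_loss(pred: Tensor, target: np.ndarray, weights: np.ndarray | None = None) -> Tensor:
    """(Weighted) mean squared error; target is a constant."""
    pred = _wrap(pred)
    t = np.asarray(target, dtype=np.float64).reshape(pred.data.shape)
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=np.float64).reshape(t.shape)
    diff = pred.data - t
    denom = w.sum()
    out = Tensor(np.array(float(np.sum(w * diff**2) / denom)), parents=(pred,))

    def bw(g):
        if pred.requires_grad:
            pred._accum(g * 2.0 * w * diff / denom)

    out._backward = bw
    return out


def cross_entropy_logits(logits: Tensor, targets: np.ndarray, candidate_mask: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over masked candidate sets.

    ``candidate_mask[i, j]`` is True when column j participates in row i's
    softmax (used to exclude each anchor's own view in the contrastive loss).
    """
    logits = _wrap(logits)
    t = np.asarray(targets, dtype=int)
    mask = np.asarray(candidate_mask, dtype=bool)
    z = np.where(mask, logits.data, -np.inf)
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    denom = ez.sum(axis=1, keepdims=True)
    logp = (z - zmax) - np.log(denom)
    n = z.shape[0]
    out = Tensor(np.array(float(-logp[np.arange(n), t].mean())), parents=(logits,))

    def bw(g):
        if logits.requires_grad:
            p = ez / denom
            p[np.arange(n), t] -= 1.0
            p[~mask] = 0.0
            logits._accum(g * p / n)

    out._backward = bw
    return out


def mean_all(a: Tensor) -> Tensor:
    a = _wrap(a)
    out = Tensor(np.array(float(a.data.mean())), parents=(a,))

    def bw(g):
        if a.requires_grad:
            a._accum(np.full_like(a.data, g / a.data.size))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# parameters and optimization


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)

    def zero_grad(self):
        self.grad = None


class Adam:
    """Adam optimizer over a dict of Parameters."""

    def __init__(self, params: dict[str, Parameter], lr: float = 1e-2, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
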