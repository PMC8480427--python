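"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just the operations the bipartite message-passing network needs: dense
matmul, bias add, ReLU, column concatenation, row gather, multiplication by a
fixed sparse matrix (used for mean neighborhood aggregation), and a mean
squared error head. Gradients are accumulated through a topologically sorted
tape; correctness is checked against central finite differences in the test
suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data: np.ndarray, parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None,
                 requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        # Backward closures hand over freshly allocated, contiguous arrays,
        # so the first contribution can be adopted without a copy.
        if self.grad is None:
            self.grad = g
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def parameter(data: np.ndarray) -> Tensor:
    data = np.asarray(data)
    if data.dtype.kind != "f":
        data = data.astype(float)
    return Tensor(data, requires_grad=True)


def constant(data: np.ndarray, dtype=None) -> Tensor:
    data = np.asarray(data, dtype=dtype)
    if data.dtype.kind != "f":
        data = data.astype(float)
    return Tensor(data)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    out._backward = backward
    return out


def add_bias(a: Tensor, b: Tensor) -> Tensor:
    """Row-broadcast bias add: (N, d) + (d,)."""
    out = Tensor(a.data + b.data, (a, b))

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g.sum(axis=0))

    out._backward = backward
    return out


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    return add_bias(matmul(x, w), b)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(np.where(mask, a.data, 0.0), (a,))

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g * mask)

    out._backward = backward
    return out


def concat(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate along the feature (last) axis."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=-1),
                 tuple(tensors))
    widths = [t.data.shape[-1] for t in tensors]
    offsets = np.cumsum([0] + widths)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accumulate(np.ascontiguousarray(g[..., lo:hi]))

    out._backward = backward
    return out


def make_scatter(idx: np.ndarray, n_rows: int, dtype=np.float64) -> sp.csr_matrix:
    """(n_rows x len(idx)) matrix that sums gathered gradients back by row.

    Prebuild once and pass to :func:`gather` when the same index array is
    reused (it is constant across message-passing layers).
    """
    idx = np.asarray(idx)
    return sp.csr_matrix((np.ones(len(idx), dtype=dtype),
                          (idx, np.arange(len(idx)))),
                         shape=(n_rows, len(idx)))


def gather(a: Tensor, idx: np.ndarray,
           scatter: sp.csr_matrix | None = None) -> Tensor:
    """Row gather a[idx]; backward scatters gradients back with accumulation."""
    idx = np.asarray(idx)
    out = Tensor(a.data[idx], (a,))

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            if scatter is not None:
                a._accumulate(scatter @ g)
            else:
                ga = np.zeros_like(a.data)
                np.add.at(ga, idx, g)
                a._accumulate(ga)

    out._backward = backward
    return out


def spmm(s: sp.spmatrix, a: Tensor) -> Tensor:
    """Multiply by a fixed (non-trainable) sparse matrix: out = S @ a."""
    s = s.tocsr()
    out = Tensor(s @ a.data, (a,))
    st = s.T.tocsr()

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(st @ g)

    out._backward = backward
    return out


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target; returns a scalar tensor."""
    target = np.asarray(target, dtype=pred.data.dtype)
    diff = pred.data - target
    out = Tensor(np.array(np.mean(diff * diff)), (pred,))

    def backward(g: np.ndarray) -> None:
        if pred.requires_grad:
            pred._accumulate((2.0 / diff.size) * diff * g)

    out._backward = backward
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, grad_clip: float | None = None) -> None:
        self.t += 1
        if grad_clip is not None:
            norm = np.sqrt(sum(float(np.sum(p.grad ** 2))
                               for p in self.params if p.grad is not None))
            scale = min(1.0, grad_clip / (norm + 1e-12))
        else:
            scale = 1.0
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
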