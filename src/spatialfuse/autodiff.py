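"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training objective composes sparse graph convolutions, dense linear maps,
rectifier/tanh nonlinearities, row-softmax attention and mean-squared errors.
This module provides exactly those operations as a tape-based autodiff
``Tensor`` so gradients never have to be derived by hand; correctness is
checked against central finite differences in the test suite.

Only what the model needs is implemented — no broadcasting rules beyond the
cases used, no higher-order derivatives.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
import scipy.sparse as sp


class Tensor:
    """Node in the computation graph.

    ``data`` is a float64 ndarray (scalars are 0-d arrays). ``grad`` is
    populated by :func:`backward`. Leaves created with ``requires_grad=True``
    are the trainable parameters.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray | float,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward_fn: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward_fn

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def constant(data: np.ndarray | float) -> Tensor:
    return Tensor(data, requires_grad=False)


def _node(data, parents, backward_fn) -> Tensor:
    needs = any(p.requires_grad or p._parents for p in parents)
    return Tensor(data, parents=tuple(parents) if needs else (),
                  backward_fn=backward_fn if needs else None)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bwd(g: np.ndarray) -> None:
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    return _node(out_data, (a, b), bwd)


def spmm(A: sp.spmatrix, x: Tensor) -> Tensor:
    """Product of a constant sparse matrix with a tensor: ``A @ x``."""
    A = A.tocsr()
    out_data = A @ x.data

    def bwd(g: np.ndarray) -> None:
        x._accumulate(A.T @ g)

    return _node(out_data, (x,), bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def bwd(g: np.ndarray) -> None:
        x._accumulate(g * mask)

    return _node(out_data, (x,), bwd)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def bwd(g: np.ndarray) -> None:
        x._accumulate(g * (1.0 - out_data**2))

    return _node(out_data, (x,), bwd)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g: np.ndarray) -> None:
        a._accumulate(g)
        b._accumulate(g)

    return _node(out_data, (a, b), bwd)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def bwd(g: np.ndarray) -> None:
        a._accumulate(g)
        b._accumulate(-g)

    return _node(out_data, (a, b), bwd)


def scale(x: Tensor, s: float) -> Tensor:
    out_data = x.data * s

    def bwd(g: np.ndarray) -> None:
        x._accumulate(g * s)

    return _node(out_data, (x,), bwd)


def add_scalar(x: Tensor, c: float) -> Tensor:
    out_data = x.data + c

    def bwd(g: np.ndarray) -> None:
        x._accumulate(g)

    return _node(out_data, (x,), bwd)


def concat_cols(xs: list[Tensor]) -> Tensor:
    """Stack N x 1 tensors into an N x M matrix."""
    out_data = np.concatenate([x.data for x in xs], axis=1)
    widths = [x.data.shape[1] for x in xs]
    offsets = np.cumsum([0] + widths)

    def bwd(g: np.ndarray) -> None:
        for x, lo, hi in zip(xs, offsets[:-1], offsets[1:]):
            x._accumulate(g[:, lo:hi])

    return _node(out_data, tuple(xs), bwd)


def softmax_rows(x: Tensor) -> Tensor:
    """Row-wise softmax of an N x M matrix."""
    shifted = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=1, keepdims=True)

    def bwd(g: np.ndarray) -> None:
        dot = (g * out_data).sum(axis=1, keepdims=True)
        x._accumulate(out_data * (g - dot))

    return _node(out_data, (x,), bwd)


def col(x: Tensor, k: int) -> Tensor:
    """Column k of an N x M matrix, as N x 1."""
    out_data = x.data[:, k : k + 1]

    def bwd(g: np.ndarray) -> None:
        full = np.zeros_like(x.data)
        full[:, k : k + 1] = g
        x._accumulate(full)

    return _node(out_data, (x,), bwd)


def rowscale(x: Tensor, w: Tensor) -> Tensor:
    """Scale each row of N x D ``x`` by the matching entry of N x 1 ``w``."""
    out_data = x.data * w.data

    def bwd(g: np.ndarray) -> None:
        x._accumulate(g * w.data)
        w._accumulate((g * x.data).sum(axis=1, keepdims=True))

    return _node(out_data, (x, w), bwd)


def add_bias(x: Tensor, b: Tensor) -> Tensor:
    """Add a 1 x D bias row to every row of N x D ``x``."""
    out_data = x.data + b.data

    def bwd(g: np.ndarray) -> None:
        x._accumulate(g)
        b._accumulate(g.sum(axis=0, keepdims=True))

    return _node(out_data, (x, b), bwd)


def add_n(xs: list[Tensor]) -> Tensor:
    out_data = xs[0].data.copy()
    for x in xs[1:]:
        out_data += x.data

    def bwd(g: np.ndarray) -> None:
        for x in xs:
            x._accumulate(g)

    return _node(out_data, tuple(xs), bwd)


def mse(a: Tensor, b: Tensor) -> Tensor:
    """Mean over rows of the squared row norms: sum((a-b)^2) / N."""
    diff = a.data - b.data
    n = a.data.shape[0]
    out_data = np.asarray((diff**2).sum() / n)

    def bwd(g: np.ndarray) -> None:
        coeff = 2.0 * float(g) / n
        a._accumulate(coeff * diff)
        b._accumulate(-coeff * diff)

    return _node(out_data, (a, b), bwd)


def backward(loss: Tensor) -> None:
    """Reverse-mode sweep seeding d(loss)/d(loss) = 1."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(loss, False)]
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
    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


def zero_grads(params: Iterable[Tensor]) -> None:
    for p in params:
        p.grad = None


class Adam:
    """Standard Adam optimizer over a list of parameter tensors."""

    def __init__(
        self,
        params: list[Tensor],
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = params
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
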