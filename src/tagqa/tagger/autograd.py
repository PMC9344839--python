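"""A minimal reverse-mode automatic differentiation engine on numpy.

Only the operations needed by the tagging heads are provided: affine
maps, pointwise nonlinearities, embedding lookups, row stacking and a
context-window concatenation.  Losses with non-trivial gradients (masked
cross-entropy, CRF negative log-likelihood) register custom backward
rules via :func:`custom_op`.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "parameter", "constant", "custom_op"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents
        self._backward = _backward

    # -- graph machinery ---------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in t._backward(g):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            else:  # leaf
                t.grad = g if t.grad is None else t.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    # -- operations --------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            return (
                (self, _unbroadcast(g, self.data.shape)),
                (other, _unbroadcast(g, other.data.shape)),
            )

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor(-self.data, _parents=(self,), _backward=lambda g: ((self, -g),))

    def __sub__(self, other) -> "Tensor":
        return self + (-_as_tensor(other))

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            return (
                (self, _unbroadcast(g * other.data, self.data.shape)),
                (other, _unbroadcast(g * self.data, other.data.shape)),
            )

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __matmul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def bw(g):
            return (
                (self, g @ other.data.T),
                (other, self.data.T @ g),
            )

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bw(g):
            return ((self, g * (1.0 - out_data**2)),)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bw(g):
            return ((self, g * out_data * (1.0 - out_data)),)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def row(self, i: int) -> "Tensor":
        """Select row ``i`` as a (1, D) tensor."""
        out_data = self.data[i : i + 1]

        def bw(g):
            full = np.zeros_like(self.data)
            full[i : i + 1] = g
            return ((self, full),)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def take_rows(self, indices) -> "Tensor":
        """Embedding-style gather of rows (duplicates accumulate grads)."""
        idx = np.asarray(indices, dtype=np.intp)
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((self, full),)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def window_concat(self, radius: int) -> "Tensor":
        """Concatenate each row with its ±radius neighbours (zero padded).

        (L, D) -> (L, (2*radius+1)*D), offsets ordered -radius..+radius.
        """
        L, D = self.data.shape
        shifts = range(-radius, radius + 1)
        cols = []
        for s in shifts:
            block = np.zeros((L, D))
            if s < 0:
                block[-s:] = self.data[: L + s]
            elif s > 0:
                block[: L - s] = self.data[s:]
            else:
                block = self.data.copy()
            cols.append(block)
        out_data = np.concatenate(cols, axis=1)

        def bw(g):
            full = np.zeros_like(self.data)
            for k, s in enumerate(shifts):
                block = g[:, k * D : (k + 1) * D]
                if s < 0:
                    full[: L + s] += block[-s:]
                elif s > 0:
                    full[s:] += block[: L - s]
                else:
                    full += block
            return ((self, full),)

        return Tensor(out_data, _parents=(self,), _backward=bw)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


def vstack(rows: Iterable[Tensor]) -> Tensor:
    """Stack (1, K) tensors into an (L, K) tensor."""
    rows = list(rows)
    out_data = np.concatenate([r.data for r in rows], axis=0)
    sizes = [r.data.shape[0] for r in rows]

    def bw(g):
        grads = []
        pos = 0
        for r, n in zip(rows, sizes):
            grads.append((r, g[pos : pos + n]))
            pos += n
        return tuple(grads)

    return Tensor(out_data, _parents=tuple(rows), _backward=bw)


def hstack(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two tensors along columns."""
    na = a.data.shape[1]
    out_data = np.concatenate([a.data, b.data], axis=1)

    def bw(g):
        return ((a, g[:, :na]), (b, g[:, na:]))

    return Tensor(out_data, _parents=(a, b), _backward=bw)


def parameter(data, rng: np.random.Generator | None = None, scale: float | None = None) -> Tensor:
    """Create a trainable leaf tensor; ``data`` may be a shape tuple."""
    if isinstance(data, tuple):
        if rng is None:
            raise ValueError("shape initialisation requires an rng")
        if scale is None:
            fan_in = data[0] if len(data) > 1 else max(data[0], 1)
            scale = 1.0 / np.sqrt(fan_in)
        data = rng.uniform(-scale, scale, size=data)
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


def custom_op(
    out_data: np.ndarray,
    parents: tuple[Tensor, ...],
    backward: Callable[[np.ndarray], tuple],
) -> Tensor:
    """Build a tensor with a hand-written backward rule.

    ``backward(grad)`` must return ``((parent, parent_grad), ...)``.
    """
    return Tensor(out_data, _parents=parents, _backward=backward)
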