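"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a small Transformer encoder: broadcasting
add/mul, batched matmul, reshape/transpose, relu/sigmoid, last-axis softmax,
layer normalization, mean reduction, dropout, and a fused
softmax-cross-entropy loss.  Everything is float64 and deterministic.

Gradient correctness of every primitive is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "softmax_cross_entropy", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus gradient bookkeeping for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))

    @classmethod
    def _make(
        cls,
        data: np.ndarray,
        parents: Sequence["Tensor"],
        backward: Callable[[np.ndarray], None],
    ) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad, dtype=float), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        a, b = self, Tensor._lift(other)

        def backward(g: np.ndarray) -> None:
            a._accumulate(g)
            b._accumulate(g)

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        a = self

        def backward(g: np.ndarray) -> None:
            a._accumulate(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        a, b = self, Tensor._lift(other)

        def backward(g: np.ndarray) -> None:
            a._accumulate(g * b.data)
            b._accumulate(g * a.data)

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar: float) -> "Tensor":
        return self * (1.0 / float(scalar))

    def matmul(self, other) -> "Tensor":
        a, b = self, Tensor._lift(other)

        def backward(g: np.ndarray) -> None:
            if a.requires_grad:
                a._accumulate(g @ np.swapaxes(b.data, -1, -2))
            if b.requires_grad:
                if b.data.ndim == 2 and g.ndim > 2:
                    # batched activations against a shared 2-D weight: one GEMM
                    # instead of materializing per-sample outer products
                    k, n = a.data.shape[-1], g.shape[-1]
                    b._accumulate(a.data.reshape(-1, k).T @ g.reshape(-1, n))
                else:
                    b._accumulate(np.swapaxes(a.data, -1, -2) @ g)

        return Tensor._make(a.data @ b.data, (a, b), backward)

    __matmul__ = matmul

    # -- shape ----------------------------------------------------------
    def reshape(self, *shape: int) -> "Tensor":
        a = self
        old = a.data.shape

        def backward(g: np.ndarray) -> None:
            a._accumulate(g.reshape(old))

        return Tensor._make(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes: int) -> "Tensor":
        a = self
        inv = np.argsort(axes)

        def backward(g: np.ndarray) -> None:
            a._accumulate(g.transpose(*inv))

        return Tensor._make(a.data.transpose(*axes), (a,), backward)

    # -- nonlinearities -------------------------------------------------
    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0

        def backward(g: np.ndarray) -> None:
            a._accumulate(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def sigmoid(self) -> "Tensor":
        a = self
        s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))

        def backward(g: np.ndarray) -> None:
            a._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (a,), backward)

    def softmax_last(self) -> "Tensor":
        """Softmax along the last axis."""
        a = self
        z = a.data - a.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)

        def backward(g: np.ndarray) -> None:
            inner = (g * s).sum(axis=-1, keepdims=True)
            a._accumulate(s * (g - inner))

        return Tensor._make(s, (a,), backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5) -> "Tensor":
        """Normalize over the last axis, then scale and shift."""
        a = self
        mu = a.data.mean(axis=-1, keepdims=True)
        xc = a.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        n = a.data.shape[-1]

        def backward(g: np.ndarray) -> None:
            gamma._accumulate((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
            beta._accumulate(g.sum(axis=tuple(range(g.ndim - 1))))
            gx = g * gamma.data
            term1 = gx
            term2 = gx.mean(axis=-1, keepdims=True)
            term3 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            a._accumulate(inv * (term1 - term2 - term3))

        return Tensor._make(
            xhat * gamma.data + beta.data, (a, gamma, beta), backward
        )

    def mean_axis(self, axis: int) -> "Tensor":
        a = self
        n = a.data.shape[axis]

        def backward(g: np.ndarray) -> None:
            a._accumulate(np.repeat(np.expand_dims(g, axis), n, axis=axis) / n)

        return Tensor._make(a.data.mean(axis=axis), (a,), backward)

    def dropout(self, p: float, rng: np.random.Generator | None) -> "Tensor":
        """Inverted dropout; identity when ``rng`` is None (evaluation mode)."""
        if rng is None or p <= 0.0:
            return self
        mask = (rng.random(self.data.shape) >= p) / (1.0 - p)
        return self * mask

    # -- graph ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-accumulate gradients from this tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=float)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain numpy softmax along the last axis (for evaluation paths)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``.

    Fused for numerical stability; gradient is (softmax - onehot) / n.
    """
    y = np.asarray(labels, dtype=int)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1))
    nll = logsumexp - z[np.arange(n), y]
    probs = np.exp(z) / np.exp(z).sum(axis=-1, keepdims=True)
    a = logits

    def backward(g: np.ndarray) -> None:
        onehot = np.zeros_like(probs)
        onehot[np.arange(n), y] = 1.0
        a._accumulate(float(g) * (probs - onehot) / n)

    return Tensor._make(np.asarray(nll.mean()), (a,), backward)
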