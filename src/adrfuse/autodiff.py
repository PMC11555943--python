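"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine sized for this package's models: dense tensors,
eager forward with recorded backward closures, and an Adam
optimizer.  Gradients are checked against central finite differences in the
test suite.

Only the operations the models need are provided.  Broadcasting follows
numpy semantics; gradients of broadcast operands are summed back to the
operand's shape.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "constant",
    "parameter",
    "concat",
    "Adam",
    "glorot",
    "dropout_mask",
    "set_dtype",
    "get_dtype",
]

# Working precision for all tensors.  float32 is the training default
# (memory-bandwidth bound workloads run ~2x faster); finite-difference
# gradient checks switch to float64.
_DTYPE = np.float32


def set_dtype(dtype) -> None:
    global _DTYPE
    if dtype not in (np.float32, np.float64):
        raise ValueError("dtype must be float32 or float64")
    _DTYPE = dtype


def get_dtype():
    return _DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph.

    ``parents`` and ``_backward`` record how to propagate the output
    gradient to the inputs; leaves created by :func:`parameter` accumulate
    gradients in ``grad``.
    """

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(
        self,
        data: np.ndarray,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        if isinstance(data, np.ndarray) and data.dtype == _DTYPE:
            self.data = data
        else:
            self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # ------------------------------------------------------------------ misc
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data / other.data, (self, other))

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = backward
        return out

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, (self,))
        out._backward = lambda g: self._accum(g * exponent * self.data ** (exponent - 1))
        return out

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, (self, other))

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                self._accum(g * b)
                other._accum(g * a)
                return
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b) if a.ndim > 1 else g * b
            if a.ndim > 2 and b.ndim == 2:
                # batched activations against a shared weight: contract the
                # batch axes directly instead of materializing per-batch grads
                axes = list(range(a.ndim - 1))
                gb = np.tensordot(a, g, axes=(axes, axes))
            else:
                gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        out._backward = backward
        return out

    # ----------------------------------------------------------- nonlinearity
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), (self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), (self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data**2))
        return out

    def sigmoid(self) -> "Tensor":
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), (self,))
        out._backward = lambda g: self._accum(g * out.data * (1.0 - out.data))
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: self._accum(g * (self.data > 0.0))
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        out = Tensor(np.where(self.data > 0.0, self.data, slope * self.data), (self,))
        out._backward = lambda g: self._accum(g * np.where(self.data > 0.0, 1.0, slope))
        return out

    def elu(self, alpha: float = 1.0) -> "Tensor":
        pos = self.data > 0.0
        out = Tensor(np.where(pos, self.data, alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)), (self,))
        out._backward = lambda g: self._accum(g * np.where(pos, 1.0, out.data + alpha))
        return out

    # ------------------------------------------------------------- reshaping
    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes: int) -> "Tensor":
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(*axes), (self,))
        out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    def gather(self, indices: np.ndarray) -> "Tensor":
        """Select rows along axis 0; duplicated indices accumulate gradient."""
        idx = np.asarray(indices)
        out = Tensor(self.data[idx], (self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = backward
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Maximum along one axis; ties share the gradient equally."""
        raw = self.data.max(axis=axis, keepdims=True)
        mask = self.data == raw
        counts = mask.sum(axis=axis, keepdims=True)
        out = Tensor(raw if keepdims else np.squeeze(raw, axis=axis), (self,))

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(g * mask / counts)

        out._backward = backward
        return out

    # --------------------------------------------------------------- special
    def masked_fill(self, mask: np.ndarray, value: float) -> "Tensor":
        """Replace entries where ``mask`` is True by a constant (no gradient there)."""
        out = Tensor(np.where(mask, value, self.data), (self,))
        out._backward = lambda g: self._accum(np.where(mask, 0.0, g))
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - constant(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def outer(self, other: "Tensor") -> "Tensor":
        """Batched outer product: (..., n) x (..., m) -> (..., n, m)."""
        other = as_tensor(other)
        out = Tensor(self.data[..., :, None] * other.data[..., None, :], (self, other))

        def backward(g):
            self._accum(_unbroadcast((g * other.data[..., None, :]).sum(-1), self.data.shape))
            other._accum(_unbroadcast((g * self.data[..., :, None]).sum(-2), other.data.shape))

        out._backward = backward
        return out

    # -------------------------------------------------------------- backward
    def _accum(self, g: np.ndarray) -> None:
        # g is always a freshly computed array (or a reshape view of one)
        # and is never mutated in place, so aliasing it is safe
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse sweep from this node; seeds with ones if no grad given."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accum(np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=_DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node is not self and not _is_leaf(node):
                node.grad = None  # free intermediate grads


def _is_leaf(t: Tensor) -> bool:
    return t._backward is None


# ------------------------------------------------------------------ factories
def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=_DTYPE))


def constant(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=_DTYPE))


def parameter(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=_DTYPE), requires_grad=True)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    out._backward = backward
    return out


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    """Glorot/Xavier uniform initialisation."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape if shape is not None else (fan_in, fan_out))


def dropout_mask(rng: np.random.Generator, shape: tuple[int, ...], p: float) -> np.ndarray:
    """Inverted-dropout multiplier: zeros with probability p, else 1/(1-p)."""
    if p <= 0.0:
        return np.ones(shape)
    return (rng.random(shape) >= p) / (1.0 - p)


class Adam:
    """Adam optimizer over a named parameter dict, with optional L2 weight decay."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-3,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * g
            self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * g**2
            mhat = self._m[k] / (1 - self.b1**self.t)
            vhat = self._v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
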