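"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: every :class:`Tensor` records the
operation that produced it and closures computing the gradient with respect
to each parent.  ``Tensor.backward()`` walks the tape in reverse topological
order and accumulates gradients into ``.grad``.  Only the operations the
segmentation network needs are implemented; each is vectorised and keeps the
input dtype (float32 throughout the model) so training stays fast on one CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An n-d array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_grad_fns")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._grad_fns: tuple = ()

    # ---------------------------------------------------------------- infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    @staticmethod
    def _make(data: np.ndarray, parents, grad_fns) -> "Tensor":
        out = Tensor(data)
        tracked = [(p, g) for p, g in zip(parents, grad_fns) if p.requires_grad]
        if tracked:
            out.requires_grad = True
            out._parents = tuple(p for p, _ in tracked)
            out._grad_fns = tuple(g for _, g in tracked)
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion limits
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, fn in zip(node._parents, node._grad_fns):
                pg = fn(g)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # ------------------------------------------------------------ arithmetic
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        data = self.data + other.data
        return Tensor._make(
            data,
            (self, other),
            (
                lambda g, s=self.shape: _unbroadcast(g, s),
                lambda g, s=other.shape: _unbroadcast(g, s),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), (lambda g: -g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        data = self.data * other.data
        return Tensor._make(
            data,
            (self, other),
            (
                lambda g, o=other.data, s=self.shape: _unbroadcast(g * o, s),
                lambda g, o=self.data, s=other.shape: _unbroadcast(g * o, s),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        data = self.data / other.data
        return Tensor._make(
            data,
            (self, other),
            (
                lambda g, o=other.data, s=self.shape: _unbroadcast(g / o, s),
                lambda g, a=self.data, o=other.data, s=other.shape: _unbroadcast(
                    -g * a / (o * o), s
                ),
            ),
        )

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        data = self.data**exponent
        return Tensor._make(
            data,
            (self,),
            (lambda g, x=self.data, n=exponent: g * n * x ** (n - 1),),
        )

    def __matmul__(self, other):
        other = self._wrap(other)
        data = self.data @ other.data
        def grad_a(g, b=other.data, s=self.shape):
            return _unbroadcast(g @ b.swapaxes(-1, -2), s)
        def grad_b(g, a=self.data, s=other.shape):
            return _unbroadcast(a.swapaxes(-1, -2) @ g, s)
        return Tensor._make(data, (self, other), (grad_a, grad_b))

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g, shape=self.shape, axis=axis, keepdims=keepdims):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, shape).astype(g.dtype)

        return Tensor._make(data, (self,), (grad_fn,))

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---------------------------------------------------------- elementwise
    def exp(self):
        data = np.exp(self.data)
        return Tensor._make(data, (self,), (lambda g, d=data: g * d,))

    def log(self):
        return Tensor._make(
            np.log(self.data), (self,), (lambda g, x=self.data: g / x,)
        )

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(data, (self,), (lambda g, d=data: g * d * (1.0 - d),))

    def tanh(self):
        data = np.tanh(self.data)
        return Tensor._make(data, (self,), (lambda g, d=data: g * (1.0 - d * d),))

    def relu(self):
        data = np.maximum(self.data, 0)
        return Tensor._make(data, (self,), (lambda g, x=self.data: g * (x > 0),))

    def gelu(self):
        """Gaussian error linear unit (tanh approximation)."""
        x = self.data
        c = float(np.sqrt(2.0 / np.pi))  # python float: no dtype promotion
        inner = c * (x + 0.044715 * (x * x * x))
        t = np.tanh(inner)
        data = 0.5 * x * (1.0 + t)

        def grad_fn(g, x=x, t=t, c=c):
            dt = (1.0 - t * t) * c * (1.0 + 3 * 0.044715 * x * x)
            return g * (0.5 * (1.0 + t) + 0.5 * x * dt)

        return Tensor._make(data, (self,), (grad_fn,))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through the interior only."""
        data = np.clip(self.data, lo, hi)
        mask = (self.data >= lo) & (self.data <= hi)
        return Tensor._make(data, (self,), (lambda g, m=mask: g * m,))

    def softmax(self, axis: int = -1):
        # shift by the (constant) max for stability; softmax is shift invariant
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        data = e / e.sum(axis=axis, keepdims=True)

        def grad_fn(g, d=data, axis=axis):
            dot = (g * d).sum(axis=axis, keepdims=True)
            return d * (g - dot)

        return Tensor._make(data, (self,), (grad_fn,))

    # --------------------------------------------------------------- shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        data = self.data.reshape(shape)
        return Tensor._make(
            data, (self,), (lambda g, s=self.shape: g.reshape(s),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        data = self.data.transpose(axes)
        return Tensor._make(data, (self,), (lambda g, inv=inv: g.transpose(inv),))

    def swapaxes(self, a: int, b: int):
        data = self.data.swapaxes(a, b)
        return Tensor._make(data, (self,), (lambda g, a=a, b=b: g.swapaxes(a, b),))

    def __getitem__(self, idx):
        data = self.data[idx]

        def grad_fn(g, idx=idx, shape=self.shape, dtype=self.data.dtype):
            out = np.zeros(shape, dtype=dtype)
            np.add.at(out, idx, g)
            return out

        return Tensor._make(data, (self,), (grad_fn,))


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Differentiable concatenation along ``axis``."""
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_fn(i):
        def grad_fn(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            return g[tuple(sl)]

        return grad_fn

    return Tensor._make(data, tuple(tensors), tuple(make_fn(i) for i in range(len(tensors))))
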