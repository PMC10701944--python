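"""Minimal reverse-mode automatic differentiation on numpy arrays.

The temporal models in this package (a bidirectional-LSTM attention network
and a small transformer) need gradients of scalar losses with respect to
embedding tables, recurrent weights and attention parameters.  This module
provides a vectorized tape-based autodiff engine: a :class:`Tensor` wraps a
numpy array, elementary operations record their inputs and a local backward
rule, and :meth:`Tensor.backward` walks the tape in reverse topological
order accumulating gradients.

Only the operations the models use are implemented.  Broadcasting follows
numpy semantics; gradients of broadcast operands are reduced back to the
operand's shape.  All computation is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concatenate",
    "stack",
    "sigmoid",
    "softmax",
    "softplus",
    "relu",
    "tanh",
    "where",
]


DTYPE = np.float64


def set_dtype(dt) -> None:
    """Set the dtype new tensors are created with (float64 default;
    float32 roughly halves training cost of the sequence models)."""
    global DTYPE
    DTYPE = np.dtype(dt).type


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to produce it."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev=(), name: str | None = None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev
        self.name = name

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            # first contribution: take an owned copy instead of zeros + add
            self.grad = np.array(np.broadcast_to(g, self.data.shape))
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS post-order (sequences can be long; avoid recursion)
        visit_stack: list[tuple[Tensor, bool]] = [(self, False)]
        while visit_stack:
            node, processed = visit_stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visit_stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    visit_stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        del stack_

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = _bw
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * out.data)

        out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = _bw
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out.data ** 2))

        out._backward = _bw
        return out

    def sigmoid(self):
        from scipy.special import expit

        s = expit(self.data)
        out = Tensor(s, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = _bw
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = _bw
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims=False):
        """Max along one axis; gradient flows to the (first) argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.max(self.data, axis=axis, keepdims=keepdims)
        out = Tensor(out_data, _prev=(self,))

        def _bw(g):
            if not self.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            grad = np.zeros_like(self.data)
            np.put_along_axis(grad, np.expand_dims(idx, axis), gg, axis=axis)
            self._accum(grad)

        out._backward = _bw
        return out

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = _bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        axes = axes or None
        out = Tensor(np.transpose(self.data, axes), _prev=(self,))
        inv = np.argsort(axes) if axes is not None else None

        def _bw(g):
            if self.requires_grad:
                self._accum(np.transpose(g, inv))

        out._backward = _bw
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _prev=(self,))
        basic = isinstance(key, (int, slice)) or (
            isinstance(key, tuple)
            and all(isinstance(k, (int, slice)) for k in key))
        gather = isinstance(key, np.ndarray) and key.dtype.kind in "iu"

        def _bw(g):
            if not self.requires_grad:
                return
            grad = np.zeros_like(self.data)
            if basic:  # no duplicate indices possible: plain assignment add
                grad[key] += g
            elif gather:  # embedding-style row gather: sparse-matmul scatter
                import scipy.sparse as _sp

                flat = key.ravel()
                tail = int(np.prod(self.data.shape[1:], dtype=np.int64)) or 1
                g2 = np.ascontiguousarray(g).reshape(-1, tail)
                sel = _sp.csr_matrix(
                    (np.ones(flat.size), flat, np.arange(flat.size + 1)),
                    shape=(flat.size, self.data.shape[0]))
                grad += (sel.T @ g2).reshape(self.data.shape)
            else:
                np.add.at(grad, key, g)
            self._accum(grad)

        out._backward = _bw
        return out


# -- free functions --------------------------------------------------------

def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = _bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _prev=tuple(tensors))

    def _bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = _bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    return Tensor._lift(x).sigmoid()


def tanh(x: Tensor) -> Tensor:
    return Tensor._lift(x).tanh()


def relu(x: Tensor) -> Tensor:
    return Tensor._lift(x).relu()


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), computed stably."""
    x = Tensor._lift(x)
    d = x.data
    s = np.maximum(d, 0) + np.log1p(np.exp(-np.abs(d)))
    out = Tensor(s, _prev=(x,))
    sig = 1.0 / (1.0 + np.exp(-d))

    def _bw(g):
        if x.requires_grad:
            x._accum(g * sig)

    out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = Tensor._lift(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, _prev=(x,))

    def _bw(g):
        if x.requires_grad:
            gs = (g * s).sum(axis=axis, keepdims=True)
            x._accum(s * (g - gs))

    out._backward = _bw
    return out


def where(mask: np.ndarray, a, b) -> Tensor:
    """Elementwise select; ``mask`` is a plain boolean array (no gradient)."""
    a = Tensor._lift(a)
    b = Tensor._lift(b)
    out = Tensor(np.where(mask, a.data, b.data), _prev=(a, b))

    def _bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~mask, b.data.shape))

    out._backward = _bw
    return out
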