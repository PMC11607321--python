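"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A small tape-based engine sufficient for fully connected networks with
parametric-rectifier activations, dropout, concatenation of view branches,
Gaussian reparameterization and the composite loss used by the multi-omic
VAE.  Only the operations the model needs are implemented; every op's
vector-Jacobian product is exercised by finite-difference tests.

Shapes follow the (samples x features) convention throughout.  Broadcasting
is supported for elementwise ops in the usual NumPy sense; gradients of
broadcast operands are summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "matmul", "maximum0", "prelu", "where_mask"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast from `shape`."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph.

    Parameters
    ----------
    data : array-like
        Value of the node, stored as float64.
    requires_grad : bool
        Whether gradients should be accumulated for this node.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._vjp = None  # callable(grad_out) -> tuple of parent grads

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data, parents, vjp) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._vjp = vjp
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic ---------------------------------------------

    def __add__(self, other):
        other = Tensor.as_tensor(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __sub__(self, other):
        other = Tensor.as_tensor(other)
        return Tensor._make(
            self.data - other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)),
        )

    def __rsub__(self, other):
        return Tensor.as_tensor(other) - self

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __pow__(self, exponent: float):
        e = float(exponent)
        return Tensor._make(
            self.data**e,
            (self,),
            lambda g: (g * e * self.data ** (e - 1.0),),
        )

    # -- unary math ----------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g / (2.0 * out_data),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * (1.0 - out_data**2),))

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(out_data, (self,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- structural -----------------------------------------------------------

    def __getitem__(self, key):
        def vjp(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return (full,)

        return Tensor._make(self.data[key], (self,), vjp)

    def reshape(self, *shape):
        orig = self.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(orig),)
        )

    @property
    def T(self):
        return Tensor._make(self.data.T, (self,), lambda g: (g.T,))

    # -- backward pass ---------------------------------------------------------

    def backward(self, grad=None):
        """Accumulate gradients of this (scalar or seeded) node into leaves."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without seed requires a scalar output")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=np.float64)

        # topological order by DFS
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

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._vjp is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._vjp(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


# -- free functions -----------------------------------------------------------


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor.as_tensor(a), Tensor.as_tensor(b)
    return Tensor._make(
        a.data @ b.data,
        (a, b),
        lambda g: (g @ b.data.T, a.data.T @ g),
    )


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        return tuple(
            np.take(g, range(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, vjp)


def maximum0(x: Tensor) -> Tensor:
    """Hinge [x]+ = max(x, 0); subgradient 0 at the kink."""
    x = Tensor.as_tensor(x)
    mask = (x.data > 0).astype(np.float64)
    return Tensor._make(x.data * mask, (x,), lambda g: (g * mask,))


def prelu(x: Tensor, slope: Tensor) -> Tensor:
    """Parametric rectifier: x if x > 0 else slope * x (scalar learnable slope)."""
    x, slope = Tensor.as_tensor(x), Tensor.as_tensor(slope)
    pos = (x.data > 0).astype(np.float64)
    neg = 1.0 - pos
    out = x.data * pos + slope.data * x.data * neg

    def vjp(g):
        gx = g * (pos + slope.data * neg)
        gs = _unbroadcast(g * x.data * neg, slope.shape)
        return gx, gs

    return Tensor._make(out, (x, slope), vjp)


def where_mask(mask: np.ndarray, x: Tensor, other: float = 0.0) -> Tensor:
    """Select x where mask else a constant; gradient flows only through mask."""
    x = Tensor.as_tensor(x)
    m = np.asarray(mask, dtype=np.float64)
    return Tensor._make(x.data * m + other * (1.0 - m), (x,), lambda g: (g * m,))
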