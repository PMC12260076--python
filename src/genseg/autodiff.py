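"""Reverse-mode automatic differentiation on numpy arrays.

This module is the numerical core of the package: a small tape-based
autodiff engine whose backward passes are themselves built from the same
differentiable operations.  Because gradients are ordinary graph nodes,
``grad(..., create_graph=True)`` can be differentiated again, which is what
the trilevel solver needs to evaluate the cross second derivatives of the
architecture hypergradient exactly.

Only the primitives required by the models in this package are provided:
broadcasting elementwise arithmetic, reductions, reshaping/transposition,
batched matrix multiplication, concatenation, and a gather/scatter pair over
flattened indices.  Convolution, padding and slicing are all expressed in
terms of gather/scatter (see :mod:`genseg.nn`), so every composite operation
supports arbitrary-order differentiation for free.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "no_grad",
    "is_grad_enabled",
    "grad",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "pow_",
    "exp",
    "log",
    "sqrt",
    "tanh",
    "sigmoid",
    "softplus",
    "sum_",
    "mean",
    "reshape",
    "transpose",
    "broadcast_to",
    "matmul",
    "concat",
    "gather_flat",
    "scatter_flat",
    "logsumexp",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Context manager disabling graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """A numpy array with an optional autodiff tape entry.

    ``_parents`` holds the input tensors of the producing operation and
    ``_backward`` maps the upstream gradient (a Tensor) to a tuple of
    gradients aligned with ``_parents`` (``None`` for non-differentiable
    inputs).  Leaves have an empty parent tuple.
    """

    __slots__ = ("data", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if arr.dtype.kind in "iub":
            arr = arr.astype(np.float64)
        self.data = arr
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def astype(self, dtype) -> "Tensor":
        def bw(g):
            return (_cast(g, self.dtype),)

        return _node(np.asarray(self.data, dtype=dtype), (self,), bw)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})\n{self.data!r}"

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return pow_(self, p)

    def __getitem__(self, key):
        idx = np.arange(self.size).reshape(self.shape)[key]
        return gather_flat(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)


def tensor(data, requires_grad=False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, _parents=parents, _backward=backward)


def _cast(g: Tensor, dtype) -> Tensor:
    def bw(up):
        return (_cast(up, g.dtype),)

    return _node(g.data.astype(dtype), (g,), bw)


# -- broadcasting helpers ----------------------------------------------

def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Sum gradient ``g`` down to ``shape`` (the adjoint of broadcasting)."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = sum_(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = reshape(g, tuple(shape))
    return g


# -- elementwise arithmetic --------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def bw(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _node(a.data + b.data, (a, b), bw)


def sub(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def bw(g):
        return _unbroadcast(g, a.shape), _unbroadcast(neg(g), b.shape)

    return _node(a.data - b.data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def bw(g):
        return _unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)

    return _node(a.data * b.data, (a, b), bw)


def div(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def bw(g):
        ga = _unbroadcast(div(g, b), a.shape)
        gb = _unbroadcast(neg(mul(g, div(a, mul(b, b)))), b.shape)
        return ga, gb

    return _node(a.data / b.data, (a, b), bw)


def neg(a) -> Tensor:
    a = _wrap(a)

    def bw(g):
        return (neg(g),)

    return _node(-a.data, (a,), bw)


def pow_(a, p: float) -> Tensor:
    a = _wrap(a)
    p = float(p)

    def bw(g):
        return (mul(g, mul(Tensor(p), pow_(a, p - 1.0))),)

    return _node(a.data ** p, (a,), bw)


def exp(a) -> Tensor:
    a = _wrap(a)
    out_data = np.exp(a.data)

    def bw(g):
        return (mul(g, out),)

    out = _node(out_data, (a,), bw)
    return out


def log(a) -> Tensor:
    a = _wrap(a)

    def bw(g):
        return (div(g, a),)

    return _node(np.log(a.data), (a,), bw)


def sqrt(a) -> Tensor:
    a = _wrap(a)

    def bw(g):
        return (div(g, mul(Tensor(2.0), out)),)

    out = _node(np.sqrt(a.data), (a,), bw)
    return out


def tanh(a) -> Tensor:
    a = _wrap(a)

    def bw(g):
        return (mul(g, sub(Tensor(1.0), mul(out, out))),)

    out = _node(np.tanh(a.data), (a,), bw)
    return out


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    sd = 1.0 / (1.0 + np.exp(-np.abs(a.data)))
    sd = np.where(a.data >= 0, sd, 1.0 - sd)

    def bw(g):
        return (mul(g, mul(out, sub(Tensor(1.0), out))),)

    out = _node(sd, (a,), bw)
    return out


def softplus(a) -> Tensor:
    """Numerically stable log(1 + exp(a)), differentiable to any order."""
    a = _wrap(a)
    pos = Tensor((a.data > 0).astype(a.dtype))  # constant branch selector
    # a*pos + log1p(exp(-|a|)); -|a| == a - 2*a*pos
    return add(mul(a, pos), log(add(Tensor(1.0), exp(sub(a, mul(Tensor(2.0), mul(a, pos)))))))


# -- reductions & shape ops --------------------------------------------

def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis % a.ndim,)
    else:
        axes = tuple(ax % a.ndim for ax in axis)

    def bw(g):
        if not keepdims:
            kd_shape = tuple(1 if i in axes else s for i, s in enumerate(a.shape))
            g = reshape(g, kd_shape)
        return (broadcast_to(g, a.shape),)

    return _node(np.sum(a.data, axis=axes, keepdims=keepdims), (a,), bw)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    if axis is None:
        n = a.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return div(sum_(a, axis=axis, keepdims=keepdims), Tensor(float(n)))


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    shape = tuple(shape)

    def bw(g):
        return (reshape(g, a.shape),)

    return _node(a.data.reshape(shape), (a,), bw)


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    axes = tuple(axes)
    inv = tuple(int(i) for i in np.argsort(axes))

    def bw(g):
        return (transpose(g, inv),)

    return _node(np.transpose(a.data, axes), (a,), bw)


def broadcast_to(a, shape) -> Tensor:
    a = _wrap(a)
    shape = tuple(shape)

    def bw(g):
        return (_unbroadcast(g, a.shape),)

    return _node(np.broadcast_to(a.data, shape).copy(), (a,), bw)


def _swap_last(x: Tensor) -> Tensor:
    axes = tuple(range(x.ndim - 2)) + (x.ndim - 1, x.ndim - 2)
    return transpose(x, axes)


def matmul(a, b) -> Tensor:
    """Batched matrix product with numpy broadcasting; operands must be >= 2-D."""
    a, b = _wrap(a), _wrap(b)
    if a.ndim < 2 or b.ndim < 2:
        raise ValueError("matmul requires operands with ndim >= 2")

    def bw(g):
        ga = _unbroadcast(matmul(g, _swap_last(b)), a.shape)
        gb = _unbroadcast(matmul(_swap_last(a), g), b.shape)
        return ga, gb

    return _node(np.matmul(a.data, b.data), (a, b), bw)


def concat(tensors, axis=0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    axis = axis % tensors[0].ndim
    sizes = [t.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bw(g):
        grads = []
        for i, t in enumerate(tensors):
            key = tuple(slice(None) if d != axis else slice(int(offs[i]), int(offs[i + 1]))
                        for d in range(t.ndim))
            grads.append(g[key])
        return tuple(grads)

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


# -- gather / scatter ---------------------------------------------------

def gather_flat(a, flat_idx) -> Tensor:
    """``a.ravel()[flat_idx]`` with shape ``flat_idx.shape``.

    ``flat_idx`` is a constant integer array; the adjoint is
    :func:`scatter_flat` with the same indices, so the pair is linear and
    differentiable to any order.
    """
    a = _wrap(a)
    flat_idx = np.asarray(flat_idx)
    in_shape, in_size = a.shape, a.size

    def bw(g):
        return (reshape(scatter_flat(g, flat_idx, in_size), in_shape),)

    return _node(a.data.reshape(-1)[flat_idx], (a,), bw)


def scatter_flat(v, flat_idx, size: int) -> Tensor:
    """Scatter-add ``v`` into a zero vector of length ``size`` at ``flat_idx``."""
    v = _wrap(v)
    flat_idx = np.asarray(flat_idx)
    if flat_idx.shape != v.shape:
        raise ValueError("scatter_flat: index shape must match value shape")

    out_data = np.bincount(flat_idx.reshape(-1), weights=v.data.reshape(-1),
                           minlength=size).astype(v.dtype, copy=False)

    def bw(g):
        return (gather_flat(g, flat_idx),)

    return _node(out_data, (v,), bw)


def logsumexp(a, axis: int, keepdims=False) -> Tensor:
    """Stable log-sum-exp along ``axis`` (shift by a constant max)."""
    a = _wrap(a)
    m = np.max(a.data, axis=axis, keepdims=True)
    shifted = sub(a, Tensor(m))
    out = add(log(sum_(exp(shifted), axis=axis, keepdims=True)), Tensor(m))
    if not keepdims:
        out = reshape(out, tuple(s for i, s in enumerate(a.shape) if i != axis % a.ndim))
    return out


# -- the gradient engine -----------------------------------------------

def _toposort(root: Tensor):
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def grad(output: Tensor, inputs, create_graph: bool = False, allow_unused: bool = True):
    """Gradients of a scalar ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own tape, so
    they can be differentiated again (needed for hypergradients).
    """
    single = isinstance(inputs, Tensor)
    inputs_list = [inputs] if single else list(inputs)
    if output.size != 1:
        raise ValueError("grad expects a scalar output")
    if not output.requires_grad:
        raise ValueError("output does not require grad")

    def run():
        grads: dict[int, Tensor] = {
            id(output): Tensor(np.ones_like(output.data))
        }
        for node in reversed(_toposort(output)):
            g = grads.get(id(node))
            if g is None or node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = add(grads[id(p)], pg)
                else:
                    grads[id(p)] = pg
        return grads

    if create_graph:
        grads = run()
    else:
        with no_grad():
            grads = run()

    out = []
    for t in inputs_list:
        g = grads.get(id(t))
        if g is None:
            if not allow_unused:
                raise ValueError("an input is unused in the graph")
            g = Tensor(np.zeros_like(t.data))
        out.append(g)
    return out[0] if single else out
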