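"""Reverse-mode automatic differentiation on NumPy arrays.

A compact tape-based engine sized for the networks in this package. Every
primitive's vector-Jacobian product is itself written in terms of primitives,
so gradients are ordinary graph nodes and higher-order derivatives (needed by
the discriminator's gradient penalty, which differentiates a gradient norm
with respect to network parameters) come out of the same machinery.

Only what the models require is implemented: broadcasting arithmetic, 2-D
matmul, reshape/transpose/slicing, reductions, exp/log, and zero-padding.
Convolutions, pooling and normalization layers are compositions of these
primitives (see :mod:`cellstyle.nn`).
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "grad",
    "tensor",
]

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    """Disable graph construction inside the context."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _grad_on():
    return _GRAD_ENABLED[-1]


class Tensor:
    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad=False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = ()
        self._vjp = None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self):
        return float(self.data)

    def numpy(self):
        return self.data

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / np.asarray(other, dtype=float))

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __pow__(self, n):
        return power(self, n)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return take(self, key)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    # -- backprop ------------------------------------------------------------
    def backward(self, grad_output=None, create_graph=False):
        """Accumulate gradients into ``.grad`` of every reachable leaf."""
        if grad_output is None:
            if self.size != 1:
                raise ValueError("backward() without grad_output requires a scalar")
            grad_output = Tensor(np.ones_like(self.data))
        gmap = _backprop(self, grad_output, create_graph=create_graph)
        for t, g in gmap:
            if t._vjp is None and t.requires_grad:
                t.grad = g if t.grad is None else add(t.grad, g)


def tensor(data, requires_grad=False):
    return Tensor(data, requires_grad=requires_grad)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, vjp):
    out = Tensor(data)
    if _grad_on() and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._vjp = vjp
    return out


def _topo(root):
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        t, done = stack.pop()
        if done:
            order.append(t)
            continue
        if id(t) in seen or t._vjp is None:
            continue
        seen.add(id(t))
        stack.append((t, True))
        for p in t._parents:
            stack.append((p, False))
    return order


def _flow(output, grad_output, create_graph):
    """Propagate ``grad_output`` through the graph; return {id(tensor): grad}."""
    order = _topo(output)
    gmap = {id(output): grad_output}
    refs = {id(output): output}
    for t in reversed(order):
        g = gmap.get(id(t))
        if g is None:
            continue
        if create_graph:
            pgrads = t._vjp(g)
        else:
            with no_grad():
                pgrads = t._vjp(g)
        for p, pg in zip(t._parents, pgrads):
            if pg is None or not p.requires_grad:
                continue
            cur = gmap.get(id(p))
            if cur is None:
                gmap[id(p)] = pg
            elif create_graph:
                gmap[id(p)] = add(cur, pg)
            else:
                with no_grad():
                    gmap[id(p)] = add(cur, pg)
            refs[id(p)] = p
    return gmap, refs


def _backprop(output, grad_output, create_graph):
    gmap, refs = _flow(output, grad_output, create_graph)
    return [(refs[i], g) for i, g in gmap.items() if i in refs]


def grad(output, inputs, grad_output=None, create_graph=False):
    """Return gradients of ``output`` w.r.t. ``inputs`` without touching .grad."""
    if grad_output is None:
        if output.size != 1:
            raise ValueError("grad() without grad_output requires a scalar output")
        grad_output = Tensor(np.ones_like(output.data))
    gmap, _ = _flow(output, grad_output, create_graph)
    out = []
    for inp in inputs:
        g = gmap.get(id(inp))
        if g is None:
            g = Tensor(np.zeros_like(inp.data))
        out.append(g)
    return out


# -- reduction of broadcast gradients ----------------------------------------

def _sum_to(g, shape):
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(
        i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1
    )
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = reshape(g, tuple(shape))
    return g


# -- primitives ---------------------------------------------------------------

def _wrap2(a, b):
    """Wrap a pair of operands, casting bare python scalars to the other
    operand's dtype so float32 graphs are not silently upcast."""
    if isinstance(a, Tensor) and not isinstance(b, Tensor):
        return a, Tensor(np.asarray(b, dtype=a.data.dtype))
    if isinstance(b, Tensor) and not isinstance(a, Tensor):
        return Tensor(np.asarray(a, dtype=b.data.dtype)), b
    return _wrap(a), _wrap(b)


def add(a, b):
    a, b = _wrap2(a, b)

    def vjp(g):
        return _sum_to(g, a.shape), _sum_to(g, b.shape)

    return _node(a.data + b.data, (a, b), vjp)


def mul(a, b):
    a, b = _wrap2(a, b)

    def vjp(g):
        ga = _sum_to(mul(g, b), a.shape) if a.requires_grad else None
        gb = _sum_to(mul(g, a), b.shape) if b.requires_grad else None
        return ga, gb

    return _node(a.data * b.data, (a, b), vjp)


def power(a, n):
    a = _wrap(a)
    n = float(n)

    def vjp(g):
        return (mul(mul(g, n), power(a, n - 1.0)),)

    return _node(a.data**n, (a,), vjp)


def exp(a):
    a = _wrap(a)

    # recompute exp(a) inside the vjp (rather than caching the forward value)
    # so the derivative keeps its dependence on `a` and double backprop is exact
    def vjp(g):
        return (mul(g, exp(a)),)

    return _node(np.exp(a.data), (a,), vjp)


def log(a):
    a = _wrap(a)

    def vjp(g):
        return (mul(g, power(a, -1.0)),)

    return _node(np.log(a.data), (a,), vjp)


def matmul(a, b):
    a, b = _wrap(a), _wrap(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")

    def vjp(g):
        ga = matmul(g, transpose(b, (1, 0))) if a.requires_grad else None
        gb = matmul(transpose(a, (1, 0)), g) if b.requires_grad else None
        return ga, gb

    return _node(a.data @ b.data, (a, b), vjp)


def reshape(a, shape):
    a = _wrap(a)
    old = a.shape

    def vjp(g):
        return (reshape(g, old),)

    return _node(a.data.reshape(shape), (a,), vjp)


def transpose(a, axes):
    a = _wrap(a)
    axes = tuple(axes)
    inv = tuple(int(i) for i in np.argsort(axes))

    def vjp(g):
        return (transpose(g, inv),)

    return _node(a.data.transpose(axes), (a,), vjp)


def tsum(a, axis=None, keepdims=False):
    a = _wrap(a)
    in_shape = a.shape
    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis,)
    else:
        axes = tuple(axis)

    def vjp(g):
        if not keepdims:
            kshape = list(in_shape)
            for ax in axes:
                kshape[ax] = 1
            g = reshape(g, tuple(kshape))
        return (broadcast_to(g, in_shape),)

    return _node(a.data.sum(axis=axes, keepdims=keepdims), (a,), vjp)


def tmean(a, axis=None, keepdims=False):
    a = _wrap(a)
    if axis is None:
        n = a.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def broadcast_to(a, shape):
    a = _wrap(a)
    old = a.shape

    def vjp(g):
        return (_sum_to(g, old),)

    return _node(np.broadcast_to(a.data, shape), (a,), vjp)


def take(a, key):
    """Basic indexing (ints and slices); each element selected at most once."""
    a = _wrap(a)
    in_shape = a.shape

    def vjp(g):
        return (put(g, in_shape, key),)

    return _node(a.data[key], (a,), vjp)


def put(a, shape, key):
    """Embed ``a`` into zeros of ``shape`` at ``key`` (adjoint of :func:`take`)."""
    a = _wrap(a)

    def vjp(g):
        return (take(g, key),)

    out = np.zeros(shape, dtype=a.data.dtype)
    out[key] = a.data
    return _node(out, (a,), vjp)


def concat(tensors, axis=0):
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def vjp(g):
        grads = []
        for t, off, sz in zip(tensors, offsets[:-1], sizes):
            key = [slice(None)] * g.ndim
            key[axis] = slice(int(off), int(off + sz))
            grads.append(take(g, tuple(key)))
        return tuple(grads)

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), vjp)


def pad2d(a, p):
    """Zero-pad the two trailing (spatial) axes by ``p`` on every side."""
    a = _wrap(a)
    if p == 0:
        return a
    b, c, h, w = a.shape
    key = (slice(None), slice(None), slice(p, p + h), slice(p, p + w))
    return put(a, (b, c, h + 2 * p, w + 2 * p), key)


# -- composed elementwise helpers ---------------------------------------------

def leaky_relu(a, slope=0.2):
    a = _wrap(a)
    scale = np.where(a.data > 0, 1.0, slope).astype(a.data.dtype)
    return mul(a, Tensor(scale))


def relu(a):
    return leaky_relu(a, 0.0)


def absolute(a):
    a = _wrap(a)
    return mul(a, Tensor(np.sign(a.data)))


def sigmoid(a):
    a = _wrap(a)
    return power(add(1.0, exp(mul(a, -1.0))), -1.0)


def sqrt(a):
    return power(a, 0.5)


def clip(a, lo, hi):
    """Clamp with straight-through zero gradient outside the interval."""
    a = _wrap(a)
    inside = ((a.data >= lo) & (a.data <= hi)).astype(a.data.dtype)
    fill = np.clip(a.data, lo, hi) * (1.0 - inside)
    return add(mul(a, Tensor(inside)), Tensor(fill))
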