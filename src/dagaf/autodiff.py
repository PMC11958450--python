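"""Minimal reverse-mode automatic differentiation on numpy arrays.

The framework's networks are small multilayer perceptrons, but the
Wasserstein critic is trained with a gradient penalty, which requires
differentiating a gradient norm with respect to the critic's parameters
(double backprop). Every vector-Jacobian product here is therefore
expressed in terms of the same traced operations, so ``grad`` with
``create_graph=True`` yields gradients that are themselves differentiable.

Only the operations the package needs are implemented: broadcast
arithmetic, (batched) matrix products, elementwise nonlinearities,
reductions, slicing/concatenation, and a trace-of-matrix-exponential node
for the acyclicity functional.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import scipy.linalg


class Tensor:
    """A numpy array plus the graph bookkeeping for reverse mode.

    ``_parents`` holds the input tensors of the op that produced this
    tensor; ``_vjps`` the matching vector-Jacobian closures, each mapping
    the upstream gradient (a Tensor) to the gradient for that parent.
    """

    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _vjps=()):
        if type(data) is np.ndarray and data.dtype == np.float64:
            self.data = data
        else:
            self.data = np.asarray(data, dtype=np.float64)
        rg = requires_grad
        if not rg:
            for p in _parents:
                if p.requires_grad:
                    rg = True
                    break
        self.requires_grad = rg
        self.grad: Tensor | None = None
        self._parents: tuple[Tensor, ...] = tuple(_parents) if rg else ()
        self._vjps: tuple[Callable, ...] = tuple(_vjps) if rg else ()

    # -- conveniences -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -astensor(other))

    def __rsub__(self, other):
        return add(astensor(other), -self)

    def __truediv__(self, other):
        return mul(self, power(astensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(astensor(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    @property
    def T(self):
        return transpose(self)

    def backward(self, gradient=None, create_graph: bool = False):
        """Accumulate gradients into ``.grad`` of every reachable leaf."""
        if gradient is None:
            gradient = Tensor(np.ones_like(self.data))
        leaves = _reachable_leaves(self)
        grads = grad(self, leaves, grad_output=gradient, create_graph=create_graph,
                     allow_unused=True)
        for leaf, g in zip(leaves, grads):
            if g is None:
                continue
            if leaf.grad is None:
                leaf.grad = g if create_graph else g.detach()
            else:
                leaf.grad = add(leaf.grad, g)
                if not create_graph:
                    leaf.grad = leaf.grad.detach()


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _reachable_leaves(root: Tensor) -> list[Tensor]:
    leaves, seen, stack = [], set(), [root]
    while stack:
        t = stack.pop()
        if id(t) in seen:
            continue
        seen.add(id(t))
        if t.requires_grad and not t._parents:
            leaves.append(t)
        stack.extend(t._parents)
    return leaves


def grad(output: Tensor, inputs: Sequence[Tensor], grad_output: Tensor | None = None,
         create_graph: bool = False, allow_unused: bool = False) -> list["Tensor | None"]:
    """Gradients of a scalar (or seeded) output w.r.t. ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own graph
    and can be differentiated again.
    """
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    # topological order of the graph above `output`
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(output, False)]
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
            if id(p) not in seen and p.requires_grad:
                stack.append((p, False))

    acc: dict[int, Tensor] = {id(output): grad_output}
    results: dict[int, Tensor] = {}
    wanted = {id(i) for i in inputs}
    for node in reversed(topo):
        g = acc.pop(id(node), None)
        if g is None:
            continue
        if id(node) in wanted:
            results[id(node)] = g
        for parent, vjp in zip(node._parents, node._vjps):
            if not parent.requires_grad:
                continue
            pg = vjp(g)
            if not create_graph:
                pg = pg.detach()
            if id(parent) in acc:
                s = add(acc[id(parent)], pg)
                acc[id(parent)] = s if create_graph else s.detach()
            else:
                acc[id(parent)] = pg
    out: list[Tensor | None] = []
    for i in inputs:
        g = results.get(id(i))
        if g is None and not allow_unused and i.requires_grad:
            g = Tensor(np.zeros_like(i.data))
        out.append(g)
    return out


# ---------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------

def _sum_to(t: Tensor, shape: tuple[int, ...]) -> Tensor:
    """Reduce a broadcasted gradient back to ``shape``."""
    if t.shape == shape:
        return t
    extra = t.ndim - len(shape)
    if extra > 0:
        t = sum_(t, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and t.shape[i] != 1)
    if axes:
        t = sum_(t, axis=axes, keepdims=True)
    if t.shape != shape:
        t = reshape(t, shape)
    return t


def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data + b.data,
        _parents=(a, b),
        _vjps=(lambda g: _sum_to(g, a.shape), lambda g: _sum_to(g, b.shape)),
    )


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data * b.data,
        _parents=(a, b),
        _vjps=(
            lambda g: _sum_to(mul(g, b), a.shape),
            lambda g: _sum_to(mul(g, a), b.shape),
        ),
    )


def power(a, p: float) -> Tensor:
    a = astensor(a)
    return Tensor(
        a.data ** p,
        _parents=(a,),
        _vjps=(lambda g: mul(g, mul(power(a, p - 1.0), p)),),
    )


def square(a) -> Tensor:
    a = astensor(a)
    return mul(a, a)


def exp(a) -> Tensor:
    a = astensor(a)
    return Tensor(np.exp(a.data), _parents=(a,), _vjps=(lambda g: mul(g, exp(a)),))


def log(a) -> Tensor:
    a = astensor(a)
    return Tensor(np.log(a.data), _parents=(a,), _vjps=(lambda g: mul(g, power(a, -1.0)),))


def sqrt(a) -> Tensor:
    a = astensor(a)
    return power(a, 0.5)


def sin(a) -> Tensor:
    a = astensor(a)
    return Tensor(np.sin(a.data), _parents=(a,), _vjps=(lambda g: mul(g, cos(a)),))


def cos(a) -> Tensor:
    a = astensor(a)
    return Tensor(np.cos(a.data), _parents=(a,), _vjps=(lambda g: mul(g, mul(sin(a), -1.0)),))


def tanh(a) -> Tensor:
    a = astensor(a)
    return Tensor(
        np.tanh(a.data),
        _parents=(a,),
        _vjps=(lambda g: mul(g, add(1.0, mul(square(tanh(a)), -1.0))),),
    )


def sigmoid(a) -> Tensor:
    a = astensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    return Tensor(
        s,
        _parents=(a,),
        _vjps=(lambda g: mul(g, mul(sigmoid(a), add(1.0, mul(sigmoid(a), -1.0)))),),
    )


def relu(a) -> Tensor:
    a = astensor(a)
    mask = (a.data > 0).astype(np.float64)
    return Tensor(a.data * mask, _parents=(a,), _vjps=(lambda g: mul(g, Tensor(mask)),))


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = astensor(a)
    out = np.where(a.data > 0, a.data, slope * a.data)

    def vjp(g):
        factor = np.where(a.data > 0, 1.0, slope)
        return mul(g, Tensor(factor))

    return Tensor(out, _parents=(a,), _vjps=(vjp,))


def abs_(a) -> Tensor:
    a = astensor(a)
    sign = np.sign(a.data)
    return Tensor(np.abs(a.data), _parents=(a,), _vjps=(lambda g: mul(g, Tensor(sign)),))


def matmul(a, b) -> Tensor:
    """Matrix product; supports stacked (batched) operands via np.matmul."""
    a, b = astensor(a), astensor(b)

    def vjp_a(g):
        return _sum_to(matmul(g, swapaxes(b, -1, -2)), a.shape)

    def vjp_b(g):
        return _sum_to(matmul(swapaxes(a, -1, -2), g), b.shape)

    return Tensor(np.matmul(a.data, b.data), _parents=(a, b), _vjps=(vjp_a, vjp_b))


def transpose(a) -> Tensor:
    a = astensor(a)
    return Tensor(a.data.T, _parents=(a,), _vjps=(lambda g: transpose(g),))


def swapaxes(a, ax1: int, ax2: int) -> Tensor:
    a = astensor(a)
    return Tensor(
        np.swapaxes(a.data, ax1, ax2),
        _parents=(a,),
        _vjps=(lambda g: swapaxes(g, ax1, ax2),),
    )


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    old = a.shape
    return Tensor(a.data.reshape(shape), _parents=(a,), _vjps=(lambda g: reshape(g, old),))


def broadcast_to(a, shape) -> Tensor:
    a = astensor(a)
    old = a.shape
    return Tensor(
        np.broadcast_to(a.data, shape).copy(),
        _parents=(a,),
        _vjps=(lambda g: _sum_to(g, old),),
    )


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    old = a.shape

    def vjp(g):
        if axis is None:
            return broadcast_to(reshape(g, (1,) * len(old)) if old else g, old)
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        axes = tuple(ax % len(old) for ax in axes)
        if not keepdims:
            shp = tuple(1 if i in axes else s for i, s in enumerate(old))
            g = reshape(g, shp)
        return broadcast_to(g, old)

    return Tensor(a.data.sum(axis=axis, keepdims=keepdims), _parents=(a,), _vjps=(vjp,))


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def getitem(a, idx) -> Tensor:
    a = astensor(a)
    shape = a.shape

    def vjp(g):
        return _scatter(g, idx, shape)

    return Tensor(a.data[idx], _parents=(a,), _vjps=(vjp,))


def _scatter(g: Tensor, idx, shape) -> Tensor:
    out = np.zeros(shape)
    np.add.at(out, idx, g.data)
    return Tensor(out, _parents=(g,), _vjps=(lambda gg: getitem(gg, idx),))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            return getitem(g, tuple(sl))

        return vjp

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _vjps=tuple(make_vjp(i) for i in range(len(tensors))),
    )


def trace_expm(a) -> Tensor:
    """tr(e^A) with d tr(e^A)/dA = (e^A)^T.

    The vjp treats the exponential as locally constant (first-order use
    only — the acyclicity penalty never sits under a second derivative).
    """
    a = astensor(a)
    if not np.all(np.isfinite(a.data)):
        raise ValueError("non-finite entries in matrix passed to trace_expm")
    with np.errstate(over="raise"):
        try:
            E = scipy.linalg.expm(a.data)
        except FloatingPointError as err:  # pragma: no cover
            raise OverflowError(
                "matrix exponential overflowed; rescale the adjacency entries"
            ) from err
    if not np.all(np.isfinite(E)):
        raise OverflowError(
            "matrix exponential overflowed; rescale the adjacency entries"
        )
    val = np.trace(E)
    ET = Tensor(E.T)
    return Tensor(val, _parents=(a,), _vjps=(lambda g: mul(g, ET),))
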