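"""Minimal reverse-mode automatic differentiation on numpy arrays.

The self-supervised fitting loop needs gradients of scalar losses with
respect to network weights, propagated through the diffusion forward
models (matrix exponent forms, the confluent hypergeometric function of
the Watson normalization, 3-D convolutions).  This module provides a
small dynamic tape: :class:`Var` wraps an ``ndarray``, records parent
nodes and a backward closure per operation, and :meth:`Var.backward`
accumulates gradients by reverse topological traversal.

Functions such as :func:`exp` or :func:`vsum` dispatch on their argument
type, so model code written against this namespace runs unchanged on
plain numpy inputs (no tape) and on :class:`Var` inputs (differentiable).
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

__all__ = [
    "Var",
    "as_var",
    "exp",
    "log",
    "sqrt",
    "sin",
    "cos",
    "arctan",
    "sigmoid",
    "relu",
    "clip_min",
    "matmul",
    "vsum",
    "vmean",
    "stack",
    "concatenate",
    "where",
    "hyp1f1_half",
    "conv3d",
    "pad_spatial",
    "grad_check",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Var:
    """A node in the computation graph: value, gradient, backward rule."""

    __slots__ = ("value", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, value, requires_grad: bool = False, _parents=(), _backward=None):
        self.value = np.asarray(value, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # ---- bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) node to all leaves."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Var] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS post-order (graphs from long training loops are deep)
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(stack_.pop())
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic --------------------------------------------------
    def __add__(self, other):
        o = as_var(other)
        out = Var(self.value + o.value, _parents=(self, o))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.value.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g, o.value.shape))

        out._backward = bwd if out.requires_grad else None
        return out

    __radd__ = __add__

    def __mul__(self, other):
        o = as_var(other)
        out = Var(self.value * o.value, _parents=(self, o))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * o.value, self.value.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g * self.value, o.value.shape))

        out._backward = bwd if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_var(other))

    def __rsub__(self, other):
        return as_var(other) + (-self)

    def __truediv__(self, other):
        o = as_var(other)
        out = Var(self.value / o.value, _parents=(self, o))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / o.value, self.value.shape))
            if o.requires_grad:
                o._accumulate(
                    _unbroadcast(-g * self.value / (o.value**2), o.value.shape)
                )

        out._backward = bwd if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return as_var(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out = Var(self.value**p, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * p * self.value ** (p - 1))

        out._backward = bwd if out.requires_grad else None
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(other, self)

    # ---- shape ops ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.value.shape
        out = Var(self.value.reshape(shape), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        out._backward = bwd if out.requires_grad else None
        return out

    def transpose(self, axes):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out = Var(self.value.transpose(axes), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = bwd if out.requires_grad else None
        return out

    @property
    def T(self):
        return self.transpose(tuple(range(self.ndim))[::-1])

    def __getitem__(self, idx):
        out = Var(self.value[idx], _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.value)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = bwd if out.requires_grad else None
        return out

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Var(shape={self.value.shape}, grad={self.requires_grad})"


def as_var(x) -> Var:
    return x if isinstance(x, Var) else Var(x)


def _is_var(*xs) -> bool:
    return any(isinstance(x, Var) for x in xs)


# ---- elementwise functions ------------------------------------------


def _unary(x, fval, fgrad):
    if not isinstance(x, Var):
        return fval(np.asarray(x, dtype=float))
    val = fval(x.value)
    out = Var(val, _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * fgrad(x.value, val))

    out._backward = bwd if out.requires_grad else None
    return out


def exp(x):
    return _unary(x, np.exp, lambda v, o: o)


def log(x):
    return _unary(x, np.log, lambda v, o: 1.0 / v)


def sqrt(x):
    return _unary(x, np.sqrt, lambda v, o: 0.5 / o)


def sin(x):
    return _unary(x, np.sin, lambda v, o: np.cos(v))


def cos(x):
    return _unary(x, np.cos, lambda v, o: -np.sin(v))


def arctan(x):
    return _unary(x, np.arctan, lambda v, o: 1.0 / (1.0 + v**2))


def _sigmoid_np(v):
    out = np.empty_like(v)
    pos = v >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
    ev = np.exp(v[~pos])
    out[~pos] = ev / (1.0 + ev)
    return out


def sigmoid(x):
    return _unary(x, _sigmoid_np, lambda v, o: o * (1.0 - o))


def relu(x):
    return _unary(x, lambda v: np.maximum(v, 0.0), lambda v, o: (v > 0).astype(float))


def clip_min(x, lo: float):
    """max(x, lo); gradient passes only where x > lo."""
    return _unary(
        x, lambda v: np.maximum(v, lo), lambda v, o: (v > lo).astype(float)
    )


def clip(x, lo: float, hi: float):
    """Clamp to [lo, hi]; gradient passes only strictly inside."""
    return _unary(
        x,
        lambda v: np.clip(v, lo, hi),
        lambda v, o: ((v > lo) & (v < hi)).astype(float),
    )


def where(cond, a, b):
    cond = np.asarray(cond)
    if not _is_var(a, b):
        return np.where(cond, a, b)
    a, b = as_var(a), as_var(b)
    out = Var(np.where(cond, a.value, b.value), _parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(np.where(cond, g, 0.0), a.value.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(np.where(cond, 0.0, g), b.value.shape))

    out._backward = bwd if out.requires_grad else None
    return out


# ---- linear algebra / reductions ------------------------------------


def matmul(a, b):
    if not _is_var(a, b):
        return np.matmul(a, b)
    a, b = as_var(a), as_var(b)
    out = Var(a.value @ b.value, _parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.value, -1, -2) if b.value.ndim > 1 else np.outer(g, b.value)
            a._accumulate(_unbroadcast(ga, a.value.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.value, -1, -2) @ g if a.value.ndim > 1 else np.outer(a.value, g)
            b._accumulate(_unbroadcast(gb, b.value.shape))

    out._backward = bwd if out.requires_grad else None
    return out


def vsum(x, axis=None, keepdims=False):
    if not isinstance(x, Var):
        return np.sum(x, axis=axis, keepdims=keepdims)
    out = Var(x.value.sum(axis=axis, keepdims=keepdims), _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            if axis is None:
                x._accumulate(np.broadcast_to(g, x.value.shape).copy())
            else:
                ax = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                x._accumulate(np.broadcast_to(g, x.value.shape).copy())

    out._backward = bwd if out.requires_grad else None
    return out


def vmean(x, axis=None, keepdims=False):
    if not isinstance(x, Var):
        return np.mean(x, axis=axis, keepdims=keepdims)
    if axis is None:
        n = x.value.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([x.value.shape[a] for a in ax]))
    return vsum(x, axis=axis, keepdims=keepdims) * (1.0 / n)


def stack(xs, axis=0):
    if not _is_var(*xs):
        return np.stack(xs, axis=axis)
    xs = [as_var(x) for x in xs]
    out = Var(np.stack([x.value for x in xs], axis=axis), _parents=tuple(xs))

    def bwd(g):
        parts = np.split(g, len(xs), axis=axis)
        for x, p in zip(xs, parts):
            if x.requires_grad:
                x._accumulate(np.squeeze(p, axis=axis))

    out._backward = bwd if out.requires_grad else None
    return out


def concatenate(xs, axis=0):
    if not _is_var(*xs):
        return np.concatenate(xs, axis=axis)
    xs = [as_var(x) for x in xs]
    out = Var(np.concatenate([x.value for x in xs], axis=axis), _parents=tuple(xs))
    sizes = [x.value.shape[axis] for x in xs]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for x, p in zip(xs, np.split(g, splits, axis=axis)):
            if x.requires_grad:
                x._accumulate(p)

    out._backward = bwd if out.requires_grad else None
    return out


# ---- special functions ----------------------------------------------


def hyp1f1_half(x, a: float = 0.5, b: float = 1.5):
    """Confluent hypergeometric ₁F₁(a; b; x), differentiable in ``x``.

    The derivative uses d/dx ₁F₁(a,b,x) = (a/b) ₁F₁(a+1,b+1,x); for the
    Watson normalization (a=0.5, b=1.5) this is the (1/3)·₁F₁(1.5,2.5,x)
    identity used to back-propagate through the concentration parameter.
    """
    if not isinstance(x, Var):
        return _sp.hyp1f1(a, b, np.asarray(x, dtype=float))
    val = _sp.hyp1f1(a, b, x.value)
    out = Var(val, _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * (a / b) * _sp.hyp1f1(a + 1.0, b + 1.0, x.value))

    out._backward = bwd if out.requires_grad else None
    return out


# ---- 3-D convolution -------------------------------------------------


def _conv3d_forward(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Valid cross-correlation: x (Cin,X,Y,Z), w (Cout,Cin,k,k,k)."""
    k = w.shape[-1]
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k, k), axis=(1, 2, 3))
    # win: (Cin, X', Y', Z', k,k,k) -> (X',Y',Z', Cin*k^3)
    win = win.transpose(1, 2, 3, 0, 4, 5, 6)
    sp = win.shape[:3]
    cols = win.reshape(*sp, -1)
    out = cols @ w.reshape(w.shape[0], -1).T  # (X',Y',Z',Cout)
    return np.ascontiguousarray(out.transpose(3, 0, 1, 2))


def conv3d(x, w, bias=None):
    """3-D convolution (cross-correlation), 'valid' padding, stride 1.

    ``x``: (Cin, X, Y, Z); ``w``: (Cout, Cin, k, k, k); ``bias``: (Cout,).
    Zero-pad the input beforehand with :func:`pad_spatial` for a
    size-preserving layer.
    """
    if not _is_var(x, w, bias):
        out = _conv3d_forward(np.asarray(x, float), np.asarray(w, float))
        if bias is not None:
            out = out + np.asarray(bias, float)[:, None, None, None]
        return out
    xv, wv = as_var(x), as_var(w)
    bv = as_var(bias) if bias is not None else None
    parents = (xv, wv) + ((bv,) if bv is not None else ())
    val = _conv3d_forward(xv.value, wv.value)
    if bv is not None:
        val = val + bv.value[:, None, None, None]
    out = Var(val, _parents=parents)
    k = wv.value.shape[-1]

    def bwd(g):
        # g: (Cout, X', Y', Z')
        if wv.requires_grad:
            win = np.lib.stride_tricks.sliding_window_view(
                xv.value, (k, k, k), axis=(1, 2, 3)
            )  # (Cin, X',Y',Z', k,k,k)
            gw = np.einsum("oxyz,cxyzijk->ocijk", g, win)
            wv._accumulate(gw)
        if xv.requires_grad:
            # full correlation of g with flipped kernels
            gp = np.pad(g, ((0, 0),) + ((k - 1, k - 1),) * 3)
            wflip = wv.value[:, :, ::-1, ::-1, ::-1]
            # swap in/out channels: (Cin, Cout, k,k,k)
            wswap = np.ascontiguousarray(wflip.transpose(1, 0, 2, 3, 4))
            xv._accumulate(_conv3d_forward(gp, wswap))
        if bv is not None and bv.requires_grad:
            bv._accumulate(g.sum(axis=(1, 2, 3)))

    out._backward = bwd if out.requires_grad else None
    return out


def pad_spatial(x, pad: int):
    """Zero-pad the three trailing spatial axes of (C, X, Y, Z)."""
    widths = ((0, 0),) + ((pad, pad),) * 3
    if not isinstance(x, Var):
        return np.pad(np.asarray(x, float), widths)
    out = Var(np.pad(x.value, widths), _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            sl = (slice(None),) + (slice(pad, -pad if pad else None),) * 3
            x._accumulate(g[sl])

    out._backward = bwd if out.requires_grad else None
    return out


# ---- verification helper --------------------------------------------


def grad_check(fn, x0: np.ndarray, eps: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Return (autodiff gradient, central-difference gradient) of scalar fn."""
    leaf = Var(x0.copy(), requires_grad=True)
    out = fn(leaf)
    out.backward()
    auto = leaf.grad.copy()
    num = np.zeros_like(x0, dtype=float)
    flat = x0.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        xp = x0.copy().reshape(-1)
        xp[i] = orig + eps
        xm = x0.copy().reshape(-1)
        xm[i] = orig - eps
        fp = fn(Var(xp.reshape(x0.shape))).value
        fm = fn(Var(xm.reshape(x0.shape))).value
        num.reshape(-1)[i] = (float(fp) - float(fm)) / (2 * eps)
    return auto, num
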