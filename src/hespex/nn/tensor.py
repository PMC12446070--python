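"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar loss walks the recorded graph
in reverse topological order and accumulates gradients into every tensor
created with ``requires_grad=True``.  The op set is deliberately small: dense
linear algebra, broadcasting arithmetic, the activations and reductions a
convolutional multitask network needs, plus the structured ops (conv2d,
pooling, upsampling, label pooling) defined in :mod:`hespex.nn.layers`.

All data is kept in float64.  This engine favours clarity and numerical
robustness over speed of deep stacks; it is fast enough for the patch sizes
this package trains on because every op is a whole-array numpy call.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self.prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self.prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")
    __array_priority__ = 100  # keep numpy from hijacking binary ops

    def __init__(self, data, requires_grad: bool = False, _prev=(), name: str = ""):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._prev = _prev if self.requires_grad else ()
        self.name = name

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _result(data, parents, backward):
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req,
                     _prev=tuple(p for p in parents if p.requires_grad) if req else ())
        if req:
            out._backward = backward
        return out

    # -- bookkeeping ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            # copy: the buffer may be shared with another consumer's gradient
            self.grad = np.array(np.broadcast_to(grad, self.data.shape),
                                 dtype=self.data.dtype)
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._prev:
                    stack.append((p, False))

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):  # weak scalar: preserves dtype
            a = self

            def bwd_s(g):
                a._accum(g)

            return Tensor._result(a.data + other, (a,), bwd_s)
        a, b = self, Tensor._wrap(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._result(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accum(-g)

        return Tensor._result(-a.data, (a,), bwd)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return (-self) + other if isinstance(other, (int, float)) \
            else Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            a = self

            def bwd_s(g):
                a._accum(g * other)

            return Tensor._result(a.data * other, (a,), bwd_s)
        a, b = self, Tensor._wrap(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._result(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        a, b = self, Tensor._wrap(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._result(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __pow__(self, p: float):
        a = self

        def bwd(g):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._result(a.data ** p, (a,), bwd)

    def __matmul__(self, other):
        a, b = self, Tensor._wrap(other)
        a1, b1 = a.data.ndim == 1, b.data.ndim == 1

        def bwd(g):
            # promote 1-D operands to row/column matrices (numpy semantics)
            ad = a.data[None, :] if a1 else a.data
            bd = b.data[:, None] if b1 else b.data
            gg = g
            if a1 and b1:
                gg = np.asarray(g).reshape(1, 1)
            elif a1:
                gg = np.expand_dims(g, -2)
            elif b1:
                gg = np.expand_dims(g, -1)
            if a.requires_grad:
                ga = np.matmul(gg, np.swapaxes(bd, -1, -2))
                if a1:
                    ga = ga.reshape(-1, ga.shape[-1]).sum(axis=0) \
                        if ga.ndim > 2 else ga[0]
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(ad, -1, -2), gg)
                if b1:
                    gb = gb.reshape(-1, gb.shape[-1]).sum(axis=0) \
                        if gb.ndim > 2 else gb[:, 0]
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._result(np.matmul(a.data, b.data), (a, b), bwd)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            a._accum(g * mask)

        return Tensor._result(a.data * mask, (a,), bwd)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accum(g * out_data)

        return Tensor._result(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accum(g / a.data)

        return Tensor._result(np.log(a.data), (a,), bwd)

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes where x > lo (subgradient 0 at clamp)."""
        a = self
        mask = a.data > lo

        def bwd(g):
            a._accum(g * mask)

        return Tensor._result(np.maximum(a.data, lo), (a,), bwd)

    def sqrt(self):
        return self ** 0.5

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bwd(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy()
                         if np.ndim(g) == a.data.ndim else np.full_like(a.data, g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._result(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.data.shape

        def bwd(g):
            a._accum(g.reshape(orig))

        return Tensor._result(a.data.reshape(shape), (a,), bwd)

    def transpose(self, *axes):
        a = self
        axes = axes or tuple(reversed(range(a.data.ndim)))
        inv = np.argsort(axes)

        def bwd(g):
            a._accum(g.transpose(inv))

        return Tensor._result(a.data.transpose(axes), (a,), bwd)

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._result(a.data[idx], (a,), bwd)

    # -- fused numerically-stable ops -----------------------------------------
    def softmax(self, axis=-1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accum(s * (g - dot))

        return Tensor._result(s, (a,), bwd)

    def log_softmax(self, axis=-1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = z - lse
        s = np.exp(out)

        def bwd(g):
            a._accum(g - s * g.sum(axis=axis, keepdims=True))

        return Tensor._result(out, (a,), bwd)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._result(np.concatenate([t.data for t in tensors], axis=axis),
                          tuple(tensors), bwd)
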