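"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the compact curvature-map encoder: broadcasting
elementwise arithmetic, (batched) matmul, strided 2-D convolution, softmax,
reductions and shape ops, each with a hand-written backward.  Float64
throughout; deterministic given deterministic inputs.  Not a general deep
learning framework and not meant to be one.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "parameter", "conv2d", "softmax", "cat_rows"]


class Tensor:
    """A numpy array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_grad_fn")

    def __init__(self, data, requires_grad=False, parents=(), grad_fn=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._grad_fn = grad_fn  # upstream grad -> tuple of parent grads (None allowed)

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal ----------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._grad_fn is None or node.grad is None:
                continue
            grads = node._grad_fn(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.copy()
                else:
                    parent.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ---------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data + other.data,
            parents=(self, other),
            grad_fn=lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), grad_fn=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data * other.data,
            parents=(self, other),
            grad_fn=lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data / other.data,
            parents=(self, other),
            grad_fn=lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __pow__(self, exponent: float):
        return Tensor(
            self.data**exponent,
            parents=(self,),
            grad_fn=lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor(out_data, parents=(self,), grad_fn=lambda g: (g * out_data,))

    def log(self):
        return Tensor(np.log(self.data), parents=(self,), grad_fn=lambda g: (g / self.data,))

    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, parents=(self,), grad_fn=lambda g: (g * mask,))

    # -- linear algebra ------------------------------------------------------

    def __matmul__(self, other):
        other = _as_tensor(other)

        def grad_fn(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor(np.matmul(self.data, other.data), parents=(self, other), grad_fn=grad_fn)

    # -- reductions / shape --------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def grad_fn(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), grad_fn=grad_fn)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        return Tensor(
            self.data.reshape(*shape),
            parents=(self,),
            grad_fn=lambda g: (g.reshape(self.shape),),
        )

    def transpose(self, *axes):
        inverse = np.argsort(axes)
        return Tensor(
            self.data.transpose(*axes),
            parents=(self,),
            grad_fn=lambda g: (g.transpose(*inverse),),
        )


def _as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcast gradient back down to the parent's shape."""
    grad = np.asarray(grad)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


# ---------------------------------------------------------------------------
# composite / custom ops


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def grad_fn(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return (s * (g - dot),)

    return Tensor(s, parents=(x,), grad_fn=grad_fn)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    s = np.exp(out_data)

    def grad_fn(g):
        return (g - s * g.sum(axis=axis, keepdims=True),)

    return Tensor(out_data, parents=(x,), grad_fn=grad_fn)


def cat_rows(tensors: list[Tensor]) -> Tensor:
    """Concatenate along axis 0."""
    sizes = [t.shape[0] for t in tensors]

    def grad_fn(g):
        out, start = [], 0
        for n in sizes:
            out.append(g[start : start + n])
            start += n
        return tuple(out)

    return Tensor(np.concatenate([t.data for t in tensors], axis=0), parents=tuple(tensors), grad_fn=grad_fn)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution, NCHW layout, 'valid' after optional zero padding."""
    xd = x.data
    if pad:
        xd = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    batch, _, h, wd_ = xd.shape
    out_c, in_c, kh, kw = w.shape
    ho = (h - kh) // stride + 1
    wo = (wd_ - kw) // stride + 1
    cols = np.empty((batch, in_c, kh, kw, ho, wo))
    for u in range(kh):
        for v in range(kw):
            cols[:, :, u, v] = xd[:, :, u : u + stride * ho : stride, v : v + stride * wo : stride]
    out = np.einsum("bcuvhw,ocuv->bohw", cols, w.data, optimize=True) + b.data[None, :, None, None]

    def grad_fn(g):
        gw = np.einsum("bcuvhw,bohw->ocuv", cols, g, optimize=True)
        gb = g.sum(axis=(0, 2, 3))
        gcols = np.einsum("bohw,ocuv->bcuvhw", g, w.data, optimize=True)
        gx_pad = np.zeros_like(xd)
        for u in range(kh):
            for v in range(kw):
                gx_pad[:, :, u : u + stride * ho : stride, v : v + stride * wo : stride] += gcols[:, :, u, v]
        gx = gx_pad[:, :, pad : gx_pad.shape[2] - pad, pad : gx_pad.shape[3] - pad] if pad else gx_pad
        return gx, gw, gb

    return Tensor(out, parents=(x, w, b), grad_fn=grad_fn)
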