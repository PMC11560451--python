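"""A small reverse-mode automatic-differentiation engine over NumPy.

Tape-based: every operation records its parents and a closure that
accumulates gradients into them; ``Tensor.backward`` runs the closures in
reverse topological order. Only the primitives the seizure-detection model
needs are provided (broadcasting arithmetic, matmul, indexing, concat,
reductions, ReLU/sigmoid/exp/log, a 2-D convolution); everything else in
the model is composed from these, so gradients never have to be derived by
hand elsewhere.

All computation is float64 on the CPU; with fixed seeds a forward/backward
pass is bit-reproducible.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An n-d array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- autodiff core -------------------------------------------------------

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(g, b.shape))

        return Tensor._node(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._node(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            a._accum(_unbroadcast(g * b.data, a.shape))
            b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._node(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            a._accum(_unbroadcast(g / b.data, a.shape))
            b._accum(_unbroadcast(-g * a.data / b.data**2, b.shape))

        return Tensor._node(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def bw(g):
            a._accum(g * e * a.data ** (e - 1.0))

        return Tensor._node(a.data**e, (a,), bw)

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            a._accum(_unbroadcast(np.matmul(g, np.swapaxes(b.data, -1, -2)), a.shape))
            b._accum(_unbroadcast(np.matmul(np.swapaxes(a.data, -1, -2), g), b.shape))

        return Tensor._node(np.matmul(a.data, b.data), (a, b), bw)

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape
        return Tensor._node(
            a.data.reshape(shape), (a,), lambda g: a._accum(g.reshape(old))
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = tuple(np.argsort(axes))
        return Tensor._node(
            a.data.transpose(axes), (a,), lambda g: a._accum(g.transpose(inv))
        )

    def swapaxes(self, i, j):
        a = self
        return Tensor._node(
            np.swapaxes(a.data, i, j), (a,), lambda g: a._accum(np.swapaxes(g, i, j))
        )

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._node(a.data[idx], (a,), bw)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return Tensor._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            denom = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            denom = int(np.prod([self.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)

    # -- nonlinearities ------------------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._node(a.data * mask, (a,), lambda g: a._accum(g * mask))

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._node(s, (a,), lambda g: a._accum(g * s * (1.0 - s)))

    def exp(self):
        a = self
        e = np.exp(a.data)
        return Tensor._node(e, (a,), lambda g: a._accum(g * e))

    def log(self):
        a = self
        return Tensor._node(np.log(a.data), (a,), lambda g: a._accum(g / a.data))

    def sqrt(self):
        return self**0.5

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through unclamped entries."""
        a = self
        mask = (a.data > lo) & (a.data < hi)
        return Tensor._node(
            np.clip(a.data, lo, hi), (a,), lambda g: a._accum(g * mask)
        )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max-shift treated as a constant)."""
    shift = x - x.data.max(axis=axis, keepdims=True)
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, o, s in zip(tensors, offsets, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(o, o + s)
            t._accum(g[tuple(sl)])

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = Tensor._lift(t)
        shape = list(t.shape)
        shape.insert(axis if axis >= 0 else t.ndim + 1 + axis, 1)
        expanded.append(t.reshape(tuple(shape)))
    return concat(expanded, axis=axis)


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
) -> Tensor:
    """2-D cross-correlation: ``x (B,C,H,W)`` with kernels ``w (O,C,kh,kw)``.

    Implemented by im2col + matmul; the backward pass scatters column
    gradients back with an explicit loop over the (small) kernel support.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    x, w = Tensor._lift(x), Tensor._lift(w)
    B, C, H, W = x.shape
    O, Cw, kh, kw = w.shape
    if Cw != C:
        raise ValueError(f"kernel expects {Cw} input channels, got {C}")
    s, p = int(stride), int(padding)

    if kh == kw == 1 and s == 1 and p == 0:  # pointwise: plain channel matmul
        wf = w.data.reshape(O, C)
        y = np.einsum("oc,bchw->bohw", wf, x.data, optimize=True)
        parents = [x, w]
        if b is not None:
            b = Tensor._lift(b)
            y = y + b.data.reshape(1, O, 1, 1)
            parents.append(b)

        def bw1(g):
            gm = g.reshape(B, O, H * W)
            xm = x.data.reshape(B, C, H * W)
            w._accum(
                np.einsum("bol,bcl->oc", gm, xm, optimize=True).reshape(w.shape)
            )
            if b is not None:
                b._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                x._accum(np.einsum("oc,bohw->bchw", wf, g, optimize=True))

        return Tensor._node(y, tuple(parents), bw1)

    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    # (B, C, Ho, Wo, kh, kw) -> (B*Ho*Wo, C*kh*kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * kh * kw)
    wf = w.data.reshape(O, -1)
    y = (cols @ wf.T).reshape(B, Ho * Wo, O).transpose(0, 2, 1).reshape(B, O, Ho, Wo)

    parents = [x, w]
    if b is not None:
        b = Tensor._lift(b)
        y = y + b.data.reshape(1, O, 1, 1)
        parents.append(b)

    def bw(g):
        # (B*HoWo, O)
        g2 = g.reshape(B, O, Ho * Wo).transpose(0, 2, 1).reshape(B * Ho * Wo, O)
        w._accum((g2.T @ cols).reshape(w.shape))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = (g2 @ wf).reshape(B, Ho, Wo, C, kh, kw)
            gxp = np.zeros((B, C, H + 2 * p, W + 2 * p))
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += (
                        gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            x._accum(gxp[:, :, p : p + H, p : p + W] if p else gxp)

    return Tensor._node(y, tuple(parents), bw)
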