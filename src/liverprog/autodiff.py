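"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sized for the desk-scale 3D survival networks in
this package: dense and batched matrix products, 3D convolution (im2col),
nearest-neighbor upsampling, softmax attention, reductions and pointwise
nonlinearities.  Gradients are accumulated into ``Tensor.grad`` by
:meth:`Tensor.backward`, seeded either with ones (scalar losses) or an
explicit output gradient (used by the Cox partial-likelihood training loop
and by Grad-CAM).

Float32 throughout; everything is deterministic given the inputs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv3d", "concat", "relu", "sigmoid", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    # -- graph -------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float32)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = grad.astype(np.float32)
        self.grad = grad if self.grad is None else self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- ops ---------------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + other * (-1.0)

    __radd__ = __add__
    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        """``self @ other``; supports (..., n, k) @ (k, m) and batched 3D @ 3D."""
        out_data = np.matmul(self.data, other.data)

        def bwd(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __matmul__ = matmul

    def reshape(self, *shape):
        shape = shape[0] if len(shape) == 1 and isinstance(shape[0], tuple) else shape
        src = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,),
                     backward=lambda g: self._accum(g.reshape(src)))
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        return Tensor(self.data.transpose(axes), parents=(self,),
                      backward=lambda g: self._accum(g.transpose(inv)))

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims=False):
        count = (self.data.size if axis is None
                 else np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor(self.data[idx], parents=(self,), backward=bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, parents=(x,),
                  backward=lambda g: x._accum(g * mask))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -30, 30)))
    return Tensor(s, parents=(x,), backward=lambda g: x._accum(g * s * (1 - s)))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    ex = np.exp(x.data - m)
    s = ex / ex.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))

    return Tensor(s, parents=(x,), backward=bwd)


def concat(tensors, axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor(data, parents=tuple(tensors), backward=bwd)


# ---------------------------------------------------------------------------
# 3D convolution and upsampling


def _im2col(xp: np.ndarray, k: int, stride: int):
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]  # (N,C,Do,Ho,Wo,k,k,k)
    n, c, do, ho, wo = win.shape[:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n, do * ho * wo, c * k**3)
    return np.ascontiguousarray(cols), (do, ho, wo)


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1,
           padding: int | None = None) -> Tensor:
    """3D convolution: x (N,C,D,H,W) * w (F,C,k,k,k) + b (F,)."""
    f, c, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    pad = k // 2 if padding is None else padding
    xp = np.pad(x.data, ((0, 0), (0, 0)) + ((pad, pad),) * 3) if pad else x.data
    cols, (do, ho, wo) = _im2col(xp, k, stride)
    n = x.data.shape[0]
    wmat = w.data.reshape(f, -1)
    out = cols @ wmat.T + b.data  # (N, L, F)
    out_data = out.transpose(0, 2, 1).reshape(n, f, do, ho, wo)

    def bwd(g):
        gl = g.reshape(n, f, -1).transpose(0, 2, 1)  # (N, L, F)
        if w.requires_grad:
            gw = np.einsum("nlf,nlc->fc", gl, cols, optimize=True)
            w._accum(gw.reshape(w.data.shape))
        if b.requires_grad:
            b._accum(gl.sum(axis=(0, 1)))
        if x.requires_grad or x._parents:
            dcols = gl @ wmat  # (N, L, C*k^3)
            dwin = dcols.reshape(n, do, ho, wo, c, k, k, k).transpose(
                0, 4, 1, 2, 3, 5, 6, 7)
            dxp = np.zeros_like(xp)
            for dz in range(k):
                for dy in range(k):
                    for dx_ in range(k):
                        dxp[:, :,
                            dz:dz + do * stride:stride,
                            dy:dy + ho * stride:stride,
                            dx_:dx_ + wo * stride:stride] += dwin[..., dz, dy, dx_]
            if pad:
                dxp = dxp[:, :, pad:-pad, pad:-pad, pad:-pad]
            x._accum(dxp)

    return Tensor(out_data, parents=(x, w, b), backward=bwd)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbor x2 upsampling of (N,C,D,H,W)."""
    d = x.data
    out = d.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def bwd(g):
        n, c, D, H, W = d.shape
        gr = g.reshape(n, c, D, 2, H, 2, W, 2).sum(axis=(3, 5, 7))
        x._accum(gr)

    return Tensor(out, parents=(x,), backward=bwd)
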