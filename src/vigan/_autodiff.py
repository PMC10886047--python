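"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training stack needs gradients through 3D convolutions, transposed
convolutions, normalization, SSIM windows and elementwise arithmetic, at
desk scale (16³–64³ volumes, tens of channels).  No deep-learning framework
is assumed; this module provides exactly the operator set the generator,
discriminator and differentiable losses require.

Conventions
-----------
* A :class:`Tensor` wraps a float64 ``numpy`` array plus an optional grad.
* Graph nodes record parent tensors and a backward closure; ``backward()``
  runs a topological sweep accumulating ``grad``.
* Volumes flow as ``(N, C, D, H, W)`` batches; 2D images as ``(N, C, H, W)``.
* Convolutions use im2col/col2im; kernel 4, stride 2, pad 1 halves each
  spatial axis, the transposed form doubles it.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "no_grad"]

#: Engine dtype. float32 keeps desk-scale training fast; tests that do
#: finite-difference gradient checks switch this to float64.
DTYPE = np.float32


class Tensor:
    """A differentiable array node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order
        order, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=DTYPE)}
        for t in reversed(order):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if pg is None:
                    continue
                key = id(p)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data + other.data,
            parents=(self, other),
            backward=lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data - other.data,
            parents=(self, other),
            backward=lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)),
        )

    def __rsub__(self, other):
        return self._lift(other) - self

    def __mul__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data * other.data,
            parents=(self, other),
            backward=lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data / other.data,
            parents=(self, other),
            backward=lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        return Tensor(
            self.data**p,
            parents=(self,),
            backward=lambda g: (g * p * self.data ** (p - 1),),
        )

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ----------------------------------------------------------- nonlinearity
    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, parents=(self,), backward=lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, DTYPE(1.0), DTYPE(slope))
        return Tensor(self.data * mask, parents=(self,), backward=lambda g: (g * mask,))

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return Tensor(y, parents=(self,), backward=lambda g: (g * y * (1.0 - y),))

    def abs(self):
        s = np.sign(self.data)
        return Tensor(np.abs(self.data), parents=(self,), backward=lambda g: (g * s,))

    def sqrt(self):
        y = np.sqrt(self.data)
        return Tensor(y, parents=(self,), backward=lambda g: (g * 0.5 / np.maximum(y, 1e-300),))

    # --------------------------------------------------------------- reshapes
    def reshape(self, *shape):
        return Tensor(
            self.data.reshape(*shape),
            parents=(self,),
            backward=lambda g: (g.reshape(self.shape),),
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(*axes),
            parents=(self,),
            backward=lambda g: (g.transpose(*inv),),
        )

    def matmul(self, other: "Tensor"):
        other = self._lift(other)
        return Tensor(
            self.data @ other.data,
            parents=(self, other),
            backward=lambda g: (g @ other.data.T, self.data.T @ g),
        )

    @staticmethod
    def concat(tensors, axis=1):
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            return tuple(np.split(g, splits, axis=axis))

        return Tensor(
            np.concatenate([t.data for t in tensors], axis=axis),
            parents=tuple(tensors),
            backward=bwd,
        )

    def dropout(self, rate: float, rng: np.random.Generator):
        """Inverted dropout; pass rate 0 (or training=False upstream) to disable."""
        if rate <= 0.0:
            return self
        keep = ((rng.random(self.shape) >= rate) / (1.0 - rate)).astype(DTYPE)
        return Tensor(self.data * keep, parents=(self,), backward=lambda g: (g * keep,))

    # ------------------------------------------------------------ convolution
    def conv3d(self, weight: "Tensor", bias: "Tensor | None", stride: int, pad):
        """3D cross-correlation. weight: (OC, IC, k, k, k); pad: int or per-axis (lo, hi)."""
        weight = self._lift(weight)
        x, w = self.data, weight.data
        k = w.shape[2]
        col, xp_shape = _im2col3d(x, k, stride, pad)  # (N, L, IC*k^3)
        n = x.shape[0]
        oc = w.shape[0]
        wmat = w.reshape(oc, -1)
        y = col @ wmat.T  # (N, L, OC)
        out_sp = _out_spatial(x.shape[2:], k, stride, pad)
        ydata = y.transpose(0, 2, 1).reshape(n, oc, *out_sp)
        if bias is not None:
            ydata = ydata + bias.data.reshape(1, oc, 1, 1, 1)

        def bwd(g):
            gflat = g.reshape(n, oc, -1).transpose(0, 2, 1)  # (N, L, OC)
            gw = np.tensordot(gflat, col, axes=([0, 1], [0, 1])).reshape(w.shape)
            gcol = gflat @ wmat  # (N, L, IC*k^3)
            gx = _col2im3d(gcol, x.shape, xp_shape, k, stride, pad)
            gb = g.sum(axis=(0, 2, 3, 4)) if bias is not None else None
            return (gx, gw, gb) if bias is not None else (gx, gw)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor(ydata, parents=parents, backward=bwd)

    def conv_transpose3d(self, weight: "Tensor", bias: "Tensor | None", stride: int, pad: int):
        """Transposed 3D convolution. weight: (IC, OC, k, k, k).

        out = (in - 1) * stride - 2*pad + k per axis.
        """
        weight = self._lift(weight)
        x, w = self.data, weight.data
        n, ic = x.shape[:2]
        k = w.shape[2]
        oc = w.shape[1]
        out_sp = tuple((s - 1) * stride - 2 * pad + k for s in x.shape[2:])
        # forward = data-gradient of the matching conv: scatter each input voxel * kernel
        wmat = w.reshape(ic, -1)  # (IC, OC*k^3)
        xflat = x.reshape(n, ic, -1).transpose(0, 2, 1)  # (N, L, IC)
        gcol = xflat @ wmat  # (N, L, OC*k^3)
        yshape = (n, oc, *out_sp)
        xp_shape = tuple(s + 2 * pad for s in out_sp)
        ydata = _col2im3d(gcol, yshape, (n, oc, *xp_shape), k, stride, pad)
        if bias is not None:
            ydata = ydata + bias.data.reshape(1, oc, 1, 1, 1)

        def bwd(g):
            col, _ = _im2col3d(g, k, stride, pad)  # (N, L, OC*k^3)
            gx = (col @ wmat.T).transpose(0, 2, 1).reshape(x.shape)
            gw = np.tensordot(xflat, col, axes=([0, 1], [0, 1])).reshape(w.shape)
            gb = g.sum(axis=(0, 2, 3, 4)) if bias is not None else None
            return (gx, gw, gb) if bias is not None else (gx, gw)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor(ydata, parents=parents, backward=bwd)

    def filter2d(self, kernel: np.ndarray):
        """Valid-mode 2D correlation of (N, H, W) with a fixed (kh, kw) kernel.

        The kernel is a constant (no gradient); used for SSIM windows.
        """
        x = self.data
        kh, kw = kernel.shape
        win = sliding_window_view(x, (kh, kw), axis=(1, 2))  # (N, Ho, Wo, kh, kw)
        y = np.tensordot(win, kernel, axes=([3, 4], [0, 1]))

        def bwd(g):
            gx = np.zeros_like(x)
            for i in range(kh):
                for j in range(kw):
                    gx[:, i : i + g.shape[1], j : j + g.shape[2]] += g * kernel[i, j]
            return (gx,)

        return Tensor(y, parents=(self,), backward=bwd)

    def instance_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalize each (sample, channel) over its spatial extent."""
        gamma = self._lift(gamma)
        beta = self._lift(beta)
        x = self.data
        axes = tuple(range(2, x.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        cdim = (1, -1) + (1,) * (x.ndim - 2)
        y = xhat * gamma.data.reshape(cdim) + beta.data.reshape(cdim)
        m = np.prod([x.shape[a] for a in axes])

        def bwd(g):
            gg = g * gamma.data.reshape(cdim)
            gxhat_mean = gg.mean(axis=axes, keepdims=True)
            gxhat_xhat_mean = (gg * xhat).mean(axis=axes, keepdims=True)
            gx = inv * (gg - gxhat_mean - xhat * gxhat_xhat_mean)
            ggamma = (g * xhat).sum(axis=(0,) + axes)
            gbeta = g.sum(axis=(0,) + axes)
            return gx, ggamma, gbeta

        _ = m  # spatial size folds into the mean terms above
        return Tensor(y, parents=(self, gamma, beta), backward=bwd)


class no_grad:
    """Context manager for API symmetry; the engine only builds graphs lazily,
    so evaluation code simply operates on ``Tensor(...).data`` — this exists to
    make intent explicit at call sites."""

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False


# ---------------------------------------------------------------- helpers

def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == tuple(shape):
        return g
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def _pad_spec(pad):
    """int -> symmetric; (lo, hi) -> same for all axes; 3 pairs -> per axis."""
    if isinstance(pad, int):
        return ((pad, pad),) * 3
    pad = tuple(pad)
    if len(pad) == 2 and all(isinstance(p, int) for p in pad):
        return (pad,) * 3
    return pad


def _out_spatial(spatial, k, stride, pad):
    ps = _pad_spec(pad)
    return tuple((s + lo + hi - k) // stride + 1 for s, (lo, hi) in zip(spatial, ps))


def _im2col3d(x, k, stride, pad):
    """(N, C, D, H, W) -> (N, L, C*k^3) of sliding windows; returns padded shape too."""
    ps = _pad_spec(pad)
    xp = np.pad(x, ((0, 0), (0, 0)) + ps)
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]  # (N, C, Do, Ho, Wo, k, k, k)
    n, c = x.shape[:2]
    do, ho, wo = win.shape[2:5]
    col = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n, do * ho * wo, c * k**3)
    return np.ascontiguousarray(col), xp.shape


def _col2im3d(gcol, xshape, xp_shape, k, stride, pad):
    """Adjoint of _im2col3d: scatter-add window gradients back to (N, C, D, H, W)."""
    ps = _pad_spec(pad)
    n, c = xshape[:2]
    out_sp = _out_spatial(xshape[2:], k, stride, pad)
    do, ho, wo = out_sp
    g = gcol.reshape(n, do, ho, wo, c, k, k, k).transpose(0, 4, 1, 2, 3, 5, 6, 7)
    gxp = np.zeros((n, c) + tuple(xp_shape[2:]), dtype=DTYPE)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                gxp[
                    :,
                    :,
                    i : i + stride * do : stride,
                    j : j + stride * ho : stride,
                    l : l + stride * wo : stride,
                ] += g[..., i, j, l]
    sl = tuple(slice(lo, lo + s) for (lo, _), s in zip(ps, xshape[2:]))
    return gxp[(slice(None), slice(None)) + sl]
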