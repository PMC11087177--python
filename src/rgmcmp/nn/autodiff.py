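"""A minimal reverse-mode automatic differentiation engine over numpy.

Supports exactly the tensor operations the segmentation networks need:
broadcast arithmetic, pointwise nonlinearities, softmax over the channel
axis, 3D convolution (arbitrary per-axis stride, 'same' zero padding),
non-overlapping transposed convolution (kernel == stride), instance
normalization, channel/spatial reductions, channel concatenation and
separable linear resampling. Tensors are single samples laid out
``(C, X, Y, Z)`` (batch size 1 throughout); all arithmetic is float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Tensor:
    """A node in the computation graph: a numpy array plus a backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph machinery --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for big networks
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def sum(self):
        return sum_all(self)

    def mean(self):
        return mul(sum_all(self), 1.0 / self.data.size)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward
    return out


def sum_all(a: Tensor) -> Tensor:
    out = Tensor(a.data.sum(), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.full_like(a.data, g))

    out._backward = backward
    return out


def log(a: Tensor) -> Tensor:
    out = Tensor(np.log(a.data), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    out._backward = backward
    return out


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes through only where values were in range."""
    out = Tensor(np.clip(a.data, lo, hi), parents=(a,))
    inside = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * inside)

    out._backward = backward
    return out


def leaky_relu(a: Tensor, alpha: float = 0.2) -> Tensor:
    pos = a.data > 0
    out = Tensor(np.where(pos, a.data, alpha * a.data), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * np.where(pos, 1.0, alpha).astype(DTYPE))

    out._backward = backward
    return out


def relu(a: Tensor) -> Tensor:
    return leaky_relu(a, 0.0)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s))

    out._backward = backward
    return out


def softmax_channels(a: Tensor) -> Tensor:
    """Softmax over axis 0 (the class/channel axis)."""
    z = a.data - a.data.max(axis=0, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=0, keepdims=True)
    out = Tensor(p, parents=(a,))

    def backward(g):
        if a.requires_grad:
            dot = (g * p).sum(axis=0, keepdims=True)
            a._accumulate(p * (g - dot))

    out._backward = backward
    return out


def concat_channels(tensors: list[Tensor]) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=0), parents=tuple(tensors))
    sizes = [t.data.shape[0] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accumulate(g[lo:hi])

    out._backward = backward
    return out


def channel_mean(a: Tensor) -> Tensor:
    """Global average pool over the spatial axes -> shape (C, 1, 1, 1)."""
    n = int(np.prod(a.data.shape[1:]))
    out = Tensor(a.data.mean(axis=(1, 2, 3), keepdims=True), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.broadcast_to(g / n, a.data.shape).astype(DTYPE))

    out._backward = backward
    return out


# -- 3D convolution ---------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: tuple[int, int, int]) -> np.ndarray:
    """(C, X, Y, Z) -> (C*k^3, P) patch matrix with 'same' zero padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    win = win[:, :: stride[0], :: stride[1], :: stride[2]]
    C = x.shape[0]
    do, ho, wo = win.shape[1:4]
    cols = win.transpose(0, 4, 5, 6, 1, 2, 3).reshape(C * k**3, do * ho * wo)
    return np.ascontiguousarray(cols), (do, ho, wo)


def _conv_dx(gy: np.ndarray, w: np.ndarray, x_shape, stride) -> np.ndarray:
    """Input gradient of the strided 'same' convolution.

    Computed as a plain convolution of the zero-dilated output gradient
    with the flipped, channel-swapped kernel — a GEMM instead of a
    scatter-add."""
    co, ci, k = w.shape[0], w.shape[1], w.shape[2]
    C, D, H, W = x_shape
    do, ho, wo = gy.shape[1:]
    sd, sh, sw = stride
    if (sd, sh, sw) == (1, 1, 1):
        gyd = gy
    else:
        gyd = np.zeros((co, D, H, W), dtype=DTYPE)
        gyd[:, : sd * do : sd, : sh * ho : sh, : sw * wo : sw] = gy
    wf = np.ascontiguousarray(w.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1])
    cols, out_dims = _im2col(gyd, k, (1, 1, 1))
    return (wf.reshape(ci, -1) @ cols).reshape(C, *out_dims)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=(1, 1, 1)) -> Tensor:
    """3D cross-correlation, 'same' padding, per-axis stride.

    ``w`` has shape (C_out, C_in, k, k, k); k must be odd.
    """
    co, ci, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    if x.data.shape[0] != ci:
        raise ValueError(f"conv3d channel mismatch: input {x.data.shape[0]}, weight {ci}")
    stride = tuple(int(s) for s in stride)
    cols, out_dims = _im2col(x.data, k, stride)
    y = w.data.reshape(co, -1) @ cols
    if b is not None:
        y = y + b.data.reshape(co, 1)
    y = y.reshape(co, *out_dims)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)

    def backward(g):
        gflat = g.reshape(co, -1)  # (Co, P)
        if w.requires_grad:
            w._accumulate((gflat @ cols.T).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gflat.sum(axis=1))
        if x.requires_grad:
            x._accumulate(_conv_dx(g, w.data, x.data.shape, stride))

    out._backward = backward
    return out


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=(2, 2, 2)) -> Tensor:
    """Transposed convolution with kernel == stride (non-overlapping blocks).

    ``w`` has shape (C_in, C_out, sd, sh, sw); output spatial size is the
    input size times the stride on each axis.
    """
    ci, co = w.data.shape[0], w.data.shape[1]
    sd, sh, sw = w.data.shape[2:]
    if x.data.shape[0] != ci:
        raise ValueError(f"conv_transpose3d channel mismatch: {x.data.shape[0]} vs {ci}")
    d, h, wd = x.data.shape[1:]
    # y[o, d*sd+a, h*sh+b, w*sw+c] = sum_i x[i,d,h,w] * w[i,o,a,b,c]
    y6 = np.einsum("idhw,ioabc->odahbwc", x.data, w.data, optimize=True)
    y = y6.reshape(co, d * sd, h * sh, wd * sw)
    if b is not None:
        y = y + b.data.reshape(co, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(np.ascontiguousarray(y), parents=parents)

    def backward(g):
        g6 = g.reshape(co, d, sd, h, sh, wd, sw)
        if x.requires_grad:
            x._accumulate(np.einsum("odahbwc,ioabc->idhw", g6, w.data, optimize=True))
        if w.requires_grad:
            w._accumulate(np.einsum("idhw,odahbwc->ioabc", x.data, g6, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(1, 2, 3)))

    out._backward = backward
    return out


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes with affine params."""
    mu = x.data.mean(axis=(1, 2, 3), keepdims=True)
    var = x.data.var(axis=(1, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gshape = (-1, 1, 1, 1)
    y = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)
    out = Tensor(y, parents=(x, gamma, beta))

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(1, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(1, 2, 3)))
        if x.requires_grad:
            gx_hat = g * gamma.data.reshape(gshape)
            m1 = gx_hat.mean(axis=(1, 2, 3), keepdims=True)
            m2 = (gx_hat * xhat).mean(axis=(1, 2, 3), keepdims=True)
            x._accumulate(inv * (gx_hat - m1 - xhat * m2))

    out._backward = backward
    return out


# -- linear resampling -------------------------------------------------------

def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1D linear-interpolation matrix (n_out × n_in), half-pixel centres."""
    a = np.zeros((n_out, n_in), dtype=DTYPE)
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (src - lo).astype(DTYPE)
    a[np.arange(n_out), lo] += 1.0 - frac
    a[np.arange(n_out), hi] += frac
    return a


def resize_linear(x: Tensor, out_spatial: tuple[int, int, int]) -> Tensor:
    """Separable trilinear resampling of (C, X, Y, Z) to a new spatial shape."""
    mats = [_interp_matrix(n_in, n_out) for n_in, n_out in zip(x.data.shape[1:], out_spatial)]
    y = np.einsum("cxyz,ax->cayz", x.data, mats[0], optimize=True)
    y = np.einsum("cxyz,by->cxbz", y, mats[1], optimize=True)
    y = np.einsum("cxyz,dz->cxyd", y, mats[2], optimize=True)
    out = Tensor(y, parents=(x,))

    def backward(g):
        if x.requires_grad:
            gx = np.einsum("cxyz,dz->cxyd", g, mats[2].T, optimize=True)
            gx = np.einsum("cxyz,by->cxbz", gx, mats[1].T, optimize=True)
            gx = np.einsum("cxyz,ax->cayz", gx, mats[0].T, optimize=True)
            x._accumulate(gx)

    out._backward = backward
    return out
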