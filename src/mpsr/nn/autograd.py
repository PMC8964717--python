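"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: float32 tensors, a static tape built during the
forward pass, and exactly the operations the restoration network needs
(convolution, deformable bilinear gathering, element-wise nonlinearities,
reductions, concatenation, nearest-neighbour upsampling).  Convolution is
im2col + GEMM; the im2col buffer is kept for the backward pass when gradients
are required and processed in row chunks otherwise, so large-tile inference
stays within a fixed memory envelope.
"""

from __future__ import annotations

import numpy as np
from contextlib import contextmanager

_GRAD_ENABLED = True

# im2col buffers above this many float32 elements are processed in chunks
# when no gradient is required (inference on large tiles).
_COL_CHUNK_ELEMS = 32_000_000


@contextmanager
def no_grad():
    """Disable tape construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32, order="C")
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- book-keeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ----------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is None or t.grad is None:
                continue
            grads = t._backward(t.grad)
            for parent, g in zip(t._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g
        # free the tape
        for t in topo:
            if t is not self:
                t._backward = None
                t._parents = ()

    # -- operator sugar ----------------------------------------------------
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

    def __neg__(self):
        return mul(self, -1.0)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == tuple(shape):
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# element-wise
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _node(out, (a, b), backward)


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data - b.data

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)

    return _node(out, (a, b), backward)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def backward(g):
        return (_unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape))

    return _node(out, (a, b), backward)


def reciprocal(a):
    a = as_tensor(a)
    out = 1.0 / a.data

    def backward(g):
        return (-g * out * out,)

    return _node(out, (a,), backward)


def absolute(a):
    a = as_tensor(a)
    out = np.abs(a.data)

    def backward(g):
        return (g * np.sign(a.data),)

    return _node(out, (a,), backward)


def leaky_relu(a, slope: float = 0.2):
    a = as_tensor(a)
    # for 0 <= slope < 1, leaky relu is max(x, slope*x)
    out = np.maximum(a.data, np.float32(slope) * a.data)

    def backward(g):
        return (np.where(a.data >= 0, g, np.float32(slope) * g),)

    return _node(out, (a,), backward)


def relu(a):
    return leaky_relu(a, 0.0)


def sigmoid(a):
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-a.data.astype(np.float64)))
    out = out.astype(np.float32)

    def backward(g):
        return (g * out * (1.0 - out),)

    return _node(out, (a,), backward)


def softplus(a):
    """log(1 + exp(x)), numerically stable."""
    a = as_tensor(a)
    x = a.data
    out = (np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x.astype(np.float64))))).astype(np.float32)

    def backward(g):
        s = 1.0 / (1.0 + np.exp(-x.astype(np.float64)))
        return (g * s.astype(np.float32),)

    return _node(out, (a,), backward)


# ---------------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------------

def mean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out = a.data.mean(axis=axis, keepdims=keepdims, dtype=np.float32)
    n = a.data.size if axis is None else np.prod([a.shape[i] for i in np.atleast_1d(axis)])

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).astype(np.float32) / np.float32(n),)

    return _node(out, (a,), backward)


def sum_(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims, dtype=np.float32)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).astype(np.float32).copy(),)

    return _node(out, (a,), backward)


def reshape(a, shape):
    a = as_tensor(a)
    out = a.data.reshape(shape)

    def backward(g):
        return (g.reshape(a.shape),)

    return _node(out, (a,), backward)


def concat(tensors, axis=1):
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]

    def backward(g):
        return tuple(np.ascontiguousarray(piece)
                     for piece in np.split(g, np.cumsum(sizes)[:-1], axis=axis))

    return _node(out, tensors, backward)


def getitem(a, idx):
    a = as_tensor(a)
    out = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        return (full,)

    return _node(out, (a,), backward)


def chan_max(a):
    """Max over the channel axis of an NCHW tensor, keepdims."""
    a = as_tensor(a)
    idx = a.data.argmax(axis=1)[:, None]
    out = np.take_along_axis(a.data, idx, axis=1)

    def backward(g):
        full = np.zeros_like(a.data)
        np.put_along_axis(full, idx, g, axis=1)
        return (full,)

    return _node(out, (a,), backward)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data

    def backward(g):
        return g @ b.data.T, a.data.T @ g

    return _node(out, (a, b), backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _pad_nchw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    B, C, H, W = x.shape
    xp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
    xp[:, :, p:p + H, p:p + W] = x
    return xp


def _stacked_weight(wdata: np.ndarray) -> np.ndarray:
    """(Cout,Cin,k,k) -> (Cout, k*k*Cin), tap-major to match the col layout."""
    cout = wdata.shape[0]
    return np.ascontiguousarray(wdata.transpose(0, 2, 3, 1).reshape(cout, -1))


def _conv_forward_chunked(xp, wdata, bias, k, stride, Ho, Wo):
    """Inference-path convolution: row-chunked im2col + GEMM.

    The column buffer for a chunk of output rows is rebuilt from the padded
    input (cache-resident across the k*k taps), so RAM traffic stays near one
    read of the input and one write of the output.
    """
    B, Cin = xp.shape[0], xp.shape[1]
    Cout = wdata.shape[0]
    wstack = _stacked_weight(wdata)
    out = np.empty((B, Cout, Ho, Wo), dtype=np.float32)
    chunk = max(8, min(Ho, 1_000_000 // max(1, Cin * k * k * Wo)))
    colbuf = np.empty((k * k * Cin, chunk * Wo), dtype=np.float32)
    for bi in range(B):
        for r0 in range(0, Ho, chunk):
            r1 = min(Ho, r0 + chunk)
            n = (r1 - r0) * Wo
            col = colbuf[:, :n].reshape(k, k, Cin, r1 - r0, Wo)
            for i in range(k):
                for j in range(k):
                    col[i, j] = xp[bi, :,
                                   stride * r0 + i:stride * (r1 - 1) + i + 1:stride,
                                   j:j + stride * Wo:stride]
            out[bi, :, r0:r1] = (wstack @ colbuf[:, :n]).reshape(Cout, r1 - r0, Wo)
    if bias is not None:
        out += bias[None, :, None, None]
    return out


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0):
    """2-D convolution (cross-correlation), NCHW layout.

    x: (B,Cin,H,W), w: (Cout,Cin,k,k), b: (Cout,) or None.
    """
    x = as_tensor(x)
    w = as_tensor(w)
    bt = as_tensor(b) if b is not None else None
    B, Cin, H, W = x.shape
    Cout, Cin_w, k, _ = w.shape
    if Cin != Cin_w:
        raise ValueError(f"conv2d channel mismatch: input {Cin}, weight {Cin_w}")
    Ho = (H + 2 * padding - k) // stride + 1
    Wo = (W + 2 * padding - k) // stride + 1
    xp = _pad_nchw(x.data, padding)

    needs_grad = _GRAD_ENABLED and (x.requires_grad or w.requires_grad
                                    or (bt is not None and bt.requires_grad))
    if not needs_grad:
        bias = bt.data if bt is not None else None
        return Tensor(_conv_forward_chunked(xp, w.data, bias, k, stride, Ho, Wo))

    # training path: one materialised column tensor, single batched GEMM
    N = Ho * Wo
    cols = np.empty((B, k * k, Cin, N), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            cols[:, i * k + j] = xp[:, :, i:i + stride * Ho:stride,
                                    j:j + stride * Wo:stride].reshape(B, Cin, N)
    cols2 = cols.reshape(B, k * k * Cin, N)
    wstack = _stacked_weight(w.data)
    out = np.matmul(wstack, cols2).reshape(B, Cout, Ho, Wo)
    if bt is not None:
        out += bt.data[None, :, None, None]

    def backward(g):
        gm = g.reshape(B, Cout, N)
        db = g.sum(axis=(0, 2, 3)) if (bt is not None and bt.requires_grad) else None
        dw = None
        if w.requires_grad:
            dws = np.matmul(gm, cols2.transpose(0, 2, 1)).sum(axis=0)  # (Cout, kkCin)
            dw = dws.reshape(Cout, k, k, Cin).transpose(0, 3, 1, 2)
            dw = np.ascontiguousarray(dw)
        dx = None
        if x.requires_grad:
            dcols = np.matmul(wstack.T, gm).reshape(B, k * k, Cin, Ho, Wo)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += \
                        dcols[:, i * k + j]
            Hp, Wp = xp.shape[2], xp.shape[3]
            dx = dxp if padding == 0 else \
                np.ascontiguousarray(dxp[:, :, padding:Hp - padding, padding:Wp - padding])
        grads = [dx, dw]
        if bt is not None:
            grads.append(db)
        return tuple(grads)

    parents = (x, w) if bt is None else (x, w, bt)
    return _node(out, parents, backward)


def upsample_nearest2x(a):
    a = as_tensor(a)
    out = a.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        B, C, H2, W2 = g.shape
        return (g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)),)

    return _node(out, (a,), backward)


def weighted_channels(w, cols):
    """out[b,o,n] = sum_c w[o,c] * cols[b,c,n] (deformable-conv contraction)."""
    w, cols = as_tensor(w), as_tensor(cols)
    out = np.matmul(w.data, cols.data)

    def backward(g):
        dw = np.matmul(g, cols.data.transpose(0, 2, 1)).sum(axis=0) if w.requires_grad else None
        dc = np.matmul(w.data.T, g) if cols.requires_grad else None
        return dw, dc

    return _node(out, (w, cols), backward)


# ---------------------------------------------------------------------------
# deformable bilinear gathering
# ---------------------------------------------------------------------------

def deform_gather(x, py, px, groups: int):
    """Bilinearly sample x at per-tap positions.

    x:  (B, C, H, W) features, C divisible by `groups`
    py: (B, G, K, Ho, Wo) absolute row positions (float)
    px: (B, G, K, Ho, Wo) absolute column positions
    returns (B, C, K, Ho, Wo); out-of-bounds taps read as zero.
    """
    x, py, px = as_tensor(x), as_tensor(py), as_tensor(px)
    B, C, H, W = x.shape
    G = groups
    Cg = C // G
    _, _, K, Ho, Wo = py.shape

    needs_grad = _GRAD_ENABLED and (x.requires_grad or py.requires_grad or px.requires_grad)
    if not needs_grad:
        from scipy.ndimage import map_coordinates
        out = np.empty((B, G, Cg, K * Ho * Wo), dtype=np.float32)
        for bi in range(B):
            for gi in range(G):
                coords = np.stack([py.data[bi, gi].ravel(), px.data[bi, gi].ravel()])
                for ci in range(Cg):
                    out[bi, gi, ci] = map_coordinates(
                        x.data[bi, gi * Cg + ci], coords, order=1,
                        mode="grid-constant", cval=0.0, output=np.float32)
        return Tensor(out.reshape(B, C, K, Ho, Wo))

    y0 = np.floor(py.data)
    x0 = np.floor(px.data)
    wy = py.data - y0
    wx = px.data - x0
    y0 = y0.astype(np.int64)
    x0 = x0.astype(np.int64)

    xf = x.data.reshape(B, G, Cg, H * W)
    corners = []
    vals = np.zeros((B, G, Cg, K, Ho, Wo), dtype=np.float32)
    for dy, dx_, wgt in (
        (0, 0, (1 - wy) * (1 - wx)),
        (0, 1, (1 - wy) * wx),
        (1, 0, wy * (1 - wx)),
        (1, 1, wy * wx),
    ):
        yc, xc = y0 + dy, x0 + dx_
        valid = (yc >= 0) & (yc < H) & (xc >= 0) & (xc < W)
        idx = np.clip(yc, 0, H - 1) * W + np.clip(xc, 0, W - 1)
        flat = idx.reshape(B, G, K * Ho * Wo)
        v = np.empty((B, G, Cg, K * Ho * Wo), dtype=np.float32)
        for bi in range(B):
            for gi in range(G):
                v[bi, gi] = xf[bi, gi][:, flat[bi, gi]]
        v = v.reshape(B, G, Cg, K, Ho, Wo)
        v *= valid[:, :, None].astype(np.float32)
        w_eff = (wgt * valid).astype(np.float32)
        vals += v * w_eff[:, :, None]
        if needs_grad:
            corners.append((idx, valid, w_eff, v))

    out = vals.reshape(B, C, K, Ho, Wo)
    if not needs_grad:
        return Tensor(out)

    def backward(g):
        gg = g.reshape(B, G, Cg, K, Ho, Wo)
        dx = None
        if x.requires_grad:
            acc = np.zeros(B * C * H * W, dtype=np.float64)
            base = (np.arange(B * G * Cg, dtype=np.int64) * (H * W)).reshape(B, G, Cg, 1, 1, 1)
            for idx, valid, w_eff, _v in corners:
                gi = base + idx[:, :, None]
                wts = (gg * w_eff[:, :, None]).astype(np.float64)
                acc += np.bincount(np.broadcast_to(gi, gg.shape).ravel(),
                                   weights=wts.ravel(), minlength=B * C * H * W)
            dx = acc.reshape(B, C, H, W).astype(np.float32)
        dpy = dpx = None
        if py.requires_grad or px.requires_grad:
            (i00, v00m, _w00, v00), (i01, v01m, _w01, v01), \
                (i10, v10m, _w10, v10), (i11, v11m, _w11, v11) = corners
            # corner values already masked to zero outside the image
            d_dy = ((1 - wx)[:, :, None] * (v10 - v00) + wx[:, :, None] * (v11 - v01))
            d_dx = ((1 - wy)[:, :, None] * (v01 - v00) + wy[:, :, None] * (v11 - v10))
            if py.requires_grad:
                dpy = (gg * d_dy).sum(axis=2)
            if px.requires_grad:
                dpx = (gg * d_dx).sum(axis=2)
        return dx, dpy, dpx

    return _node(out, (x, py, px), backward)
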