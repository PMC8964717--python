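"""Minimal neural-network modules on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class; collects parameters by attribute introspection."""

    def parameters(self) -> list[Tensor]:
        params, seen = [], set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.ascontiguousarray(a, dtype=np.float32)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_normal(rng: np.random.Generator, shape, fan_in: int, scale: float = 1.0):
    std = scale * np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Conv2d(Module):
    """3x3/kxk convolution with He initialisation (optionally rescaled)."""

    def __init__(self, cin, cout, k=3, stride=1, padding=None, bias=True,
                 rng=None, init_scale=1.0, zero_init=False):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        if zero_init:
            w = np.zeros((cout, cin, k, k), dtype=np.float32)
        else:
            w = he_normal(rng, (cout, cin, k, k), cin * k * k, init_scale)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, fin, fout, rng=None, init_scale=1.0, bias=True):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Tensor(he_normal(rng, (fout, fin), fin, init_scale), requires_grad=True)
        self.bias = Tensor(np.zeros(fout, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        out = ag.matmul(x, _transpose(self.weight))
        if self.bias is not None:
            out = ag.add(out, self.bias)
        return out


def _transpose(t: Tensor) -> Tensor:
    out = ag.Tensor(t.data.T)
    if ag.grad_enabled() and t.requires_grad:
        out.requires_grad = True
        out._parents = (t,)
        out._backward = lambda g: (g.T,)
    return out


def spectral_normalize(weight: np.ndarray, n_power_iters: int = 1, state: dict | None = None):
    """Divide a weight matrix by its largest singular value (power iteration).

    `state` persists the left/right singular-vector estimates between calls.
    A zero matrix is returned unchanged.  Returns (normalized, sigma).
    """
    w2 = weight.reshape(weight.shape[0], -1).astype(np.float64)
    norm = np.linalg.norm(w2)
    if norm == 0:
        return weight.copy(), 0.0
    if state is None:
        state = {}
    u = state.get("u")
    if u is None or u.shape[0] != w2.shape[0]:
        rng = np.random.default_rng(0)
        u = rng.standard_normal(w2.shape[0])
        u /= np.linalg.norm(u)
    v = None
    for _ in range(max(1, n_power_iters)):
        v = w2.T @ u
        v /= (np.linalg.norm(v) + 1e-12)
        u = w2 @ v
        u /= (np.linalg.norm(u) + 1e-12)
    sigma = float(u @ w2 @ v)
    state["u"] = u
    state["v"] = v
    if sigma <= 0:
        return weight.copy(), 0.0
    return (weight / sigma).astype(weight.dtype), sigma


class _SpectralMixin:
    """Shared forward-time weight normalisation for SN layers.

    One power iteration per forward call updates the persistent singular
    vectors; the division by sigma is part of the autodiff graph so the
    generator/discriminator gradients see the normalised operator.
    """

    def _normalized_weight(self) -> Tensor:
        _, sigma = spectral_normalize(self.weight.data, 1, self._sn_state)
        if sigma == 0:
            return self.weight
        u = self._sn_state["u"].astype(np.float32)
        v = self._sn_state["v"].astype(np.float32)
        cout = self.weight.shape[0]
        w2 = ag.reshape(self.weight, (cout, -1))
        sig = ag.matmul(ag.matmul(ag.Tensor(u[None, :]), w2), ag.Tensor(v[:, None]))
        inv = ag.reshape(ag.reciprocal(sig), (1,) * self.weight.ndim)
        return ag.mul(self.weight, inv)


class SNConv2d(Conv2d, _SpectralMixin):
    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self._sn_state = {}

    def forward(self, x):
        return ag.conv2d(x, self._normalized_weight(), self.bias,
                         stride=self.stride, padding=self.padding)


class SNLinear(Linear, _SpectralMixin):
    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self._sn_state = {}

    def forward(self, x):
        out = ag.matmul(x, _transpose(self._normalized_weight()))
        if self.bias is not None:
            out = ag.add(out, self.bias)
        return out


class DeformConv2d(Module):
    """3x3 deformable convolution: taps read at learned sub-pixel offsets.

    Offsets come from a separate tensor (B, 2*K*groups, H, W) laid out as
    (group, tap, [dy, dx]).  With all-zero offsets this is numerically a
    plain 3x3 convolution with the same weights.
    """

    K = 9  # 3x3 taps

    def __init__(self, cin, cout, groups=1, rng=None, init_scale=1.0, bias=True):
        rng = rng if rng is not None else np.random.default_rng(0)
        if cin % groups:
            raise ValueError("cin must be divisible by deform groups")
        self.groups = groups
        self.weight = Tensor(he_normal(rng, (cout, cin, 3, 3), cin * 9, init_scale),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x, offsets):
        B, C, H, W = x.shape
        G, K = self.groups, self.K
        off = ag.reshape(offsets, (B, G, K, 2, H, W))
        dy = ag.getitem(off, (slice(None), slice(None), slice(None), 0))
        dx = ag.getitem(off, (slice(None), slice(None), slice(None), 1))
        ii, jj = np.meshgrid(np.arange(H, dtype=np.float32),
                             np.arange(W, dtype=np.float32), indexing="ij")
        taps = np.array([(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1)], dtype=np.float32)
        base_y = ii[None, None, None] + taps[:, 0][None, None, :, None, None]
        base_x = jj[None, None, None] + taps[:, 1][None, None, :, None, None]
        py = ag.add(dy, ag.Tensor(np.broadcast_to(base_y, (1, G, K, H, W)).copy()))
        px = ag.add(dx, ag.Tensor(np.broadcast_to(base_x, (1, G, K, H, W)).copy()))
        cols = ag.deform_gather(x, py, px, G)          # (B, C, K, H, W)
        cols = ag.reshape(cols, (B, C * K, H * W))
        wmat = ag.reshape(self.weight, (self.weight.shape[0], C * K))
        out = ag.weighted_channels(wmat, cols)
        out = ag.reshape(out, (B, self.weight.shape[0], H, W))
        if self.bias is not None:
            out = ag.add(out, ag.reshape(self.bias, (1, -1, 1, 1)))
        return out


class Adam:
    """Adam optimiser (Kingma & Ba) over a parameter list."""

    def __init__(self, params: list[Tensor], lr=1e-4, betas=(0.9, 0.99), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
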