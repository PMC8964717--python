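"""Restoration generator: self-aligned, attention-guided residual dense network.

The generator maps a single-modality low-resolution raster to a x4
super-resolved one.  Stages: shallow feature extraction -> self-alignment via
a pyramid of cascaded deformable convolutions (offsets predicted from the
input features themselves, since no reference frame exists at inference) ->
a trunk of residual-in-residual dense attention blocks (RRDAB) -> global
residual skip -> two nearest-neighbour x2 upsampling stages with
convolutions -> reconstruction convolutions.

Residual-in-residual dense blocks follow the ESRGAN lineage; each block here
additionally carries squeeze-and-excitation channel attention and a spatial
attention gate between the dense stack and the outer residual.  The final
convolution of every dense sub-block and every offset head is
zero-initialised so the network starts as an identity-like mapping
(zero offsets, pass-through residuals), which stabilises early training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import Conv2d, DeformConv2d, Module


@dataclass
class GeneratorConfig:
    """Architecture hyper-parameters.

    ``base_feats`` is the trunk feature width, ``n_rrdab`` the trunk depth,
    ``growth`` the dense-block growth width, ``residual_scale`` the beta
    applied to every residual branch, ``pyramid_levels`` the number of
    self-alignment scales and ``deform_groups`` the number of independent
    offset groups of each deformable convolution.  ``upscale`` is fixed at 4
    (two x2 stages).
    """

    in_channels: int = 1
    base_feats: int = 64
    n_rrdab: int = 23
    growth: int = 32
    residual_scale: float = 0.2
    pyramid_levels: int = 3
    deform_groups: int = 8
    upscale: int = 4
    use_sapcd: bool = True   # ablation switch for the self-alignment module
    seed: int = 0

    def validate(self):
        if self.upscale != 4:
            raise ValueError("only x4 upscaling (two x2 stages) is supported")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.base_feats % self.deform_groups:
            raise ValueError("base_feats must be divisible by deform_groups")
        if self.in_channels != 1:
            raise ValueError("the generator processes one modality at a time")
        if self.n_rrdab < 0 or self.growth < 1 or self.base_feats < 1:
            raise ValueError("invalid generator size parameters")
        if not 0 < self.residual_scale <= 1:
            raise ValueError("residual_scale must lie in (0, 1]")


TINY = dict(base_feats=16, n_rrdab=2, growth=8, pyramid_levels=2, deform_groups=1)


def tiny_config(**overrides) -> GeneratorConfig:
    """Small CPU-friendly preset used throughout the test suite."""
    kw = dict(TINY)
    kw.update(overrides)
    return GeneratorConfig(**kw)


def _lrelu(x):
    return ag.leaky_relu(x, 0.2)


class DenseSubBlock(Module):
    """Five densely connected 3x3 convs; the last projects back to nf and is
    zero-initialised; output = x + beta * branch."""

    def __init__(self, nf, gc, beta, rng):
        self.beta = beta
        self.convs = [Conv2d(nf + i * gc, gc, 3, rng=rng, init_scale=0.1) for i in range(4)]
        self.conv_out = Conv2d(nf + 4 * gc, nf, 3, rng=rng, zero_init=True)

    def forward(self, x):
        feats = [x]
        for conv in self.convs:
            inp = feats[0] if len(feats) == 1 else ag.concat(feats, axis=1)
            feats.append(_lrelu(conv(inp)))
        branch = self.conv_out(ag.concat(feats, axis=1))
        return ag.add(x, ag.mul(branch, self.beta))


class ChannelAttention(Module):
    """Squeeze-and-excitation gate: global pool -> bottleneck -> sigmoid."""

    def __init__(self, nf, rng, reduction=4):
        hidden = max(nf // reduction, 4)
        self.fc1 = Conv2d(nf, hidden, 1, padding=0, rng=rng)
        self.fc2 = Conv2d(hidden, nf, 1, padding=0, rng=rng)

    def gate(self, x):
        pooled = ag.mean(x, axis=(2, 3), keepdims=True)
        return ag.sigmoid(self.fc2(ag.relu(self.fc1(pooled))))

    def forward(self, x):
        return ag.mul(x, self.gate(x))


class SpatialAttention(Module):
    """Per-pixel gate from channel-pooled statistics (mean and max maps)."""

    def __init__(self, rng, k=7):
        self.conv = Conv2d(2, 1, k, rng=rng)

    def gate(self, x):
        pooled = ag.concat([ag.mean(x, axis=1, keepdims=True), ag.chan_max(x)], axis=1)
        return ag.sigmoid(self.conv(pooled))

    def forward(self, x):
        return ag.mul(x, self.gate(x))


class RRDAB(Module):
    """Residual-in-residual dense attention block.

    Three dense sub-blocks, then channel attention and spatial attention on
    the aggregate branch, then the outer residual with scale beta.
    """

    def __init__(self, nf, gc, beta, rng):
        self.beta = beta
        self.db1 = DenseSubBlock(nf, gc, beta, rng)
        self.db2 = DenseSubBlock(nf, gc, beta, rng)
        self.db3 = DenseSubBlock(nf, gc, beta, rng)
        self.ca = ChannelAttention(nf, rng)
        self.sa = SpatialAttention(rng)

    def forward(self, x):
        t = self.db3(self.db2(self.db1(x)))
        t = self.sa(self.ca(t))
        return ag.add(x, ag.mul(t, self.beta))


class OffsetHead(Module):
    """Predicts deformable-convolution offsets from features (zero-initialised
    final layer, so offsets start at zero)."""

    def __init__(self, cin, nf, groups, rng):
        self.conv1 = Conv2d(cin, nf, 3, rng=rng, init_scale=0.1)
        self.conv2 = Conv2d(nf, 2 * 9 * groups, 3, rng=rng, zero_init=True)

    def forward(self, x):
        return self.conv2(_lrelu(self.conv1(x)))


class SAPCD(Module):
    """Self-alignment with pyramid, cascading and deformable convolutions.

    An L-level feature pyramid is built by strided convolutions.  At the
    coarsest level an offset field is predicted from the features alone and a
    deformable convolution resamples them; offsets and aligned features are
    then upsampled (offsets doubled to stay in pixels of the finer grid) and
    cascaded as priors into the next finer level.  A final deformable
    refinement runs at full resolution.  Output shape equals input shape; the
    spatial dims must be divisible by 2**(levels-1).
    """

    def __init__(self, nf, levels, groups, rng):
        self.levels = levels
        self.groups = groups
        self.downs = [Conv2d(nf, nf, 3, stride=2, rng=rng, init_scale=0.1)
                      for _ in range(levels - 1)]
        off_in = [nf if l == levels - 1 else nf + 2 * 9 * groups for l in range(levels)]
        self.offset_heads = [OffsetHead(off_in[l], nf, groups, rng) for l in range(levels)]
        self.deforms = [DeformConv2d(nf, nf, groups=groups, rng=rng, init_scale=0.1)
                        for _ in range(levels)]
        self.merges = [Conv2d(2 * nf, nf, 3, rng=rng, init_scale=0.1)
                       for _ in range(levels - 1)]
        self.refine_head = OffsetHead(nf, nf, groups, rng)
        self.refine = DeformConv2d(nf, nf, groups=groups, rng=rng, init_scale=0.1)

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        div = 2 ** (self.levels - 1)
        if h % div or w % div:
            raise ValueError(f"spatial dims must be divisible by {div} for "
                             f"{self.levels} pyramid levels, got {h}x{w}")
        feats = [x]
        for down in self.downs:
            feats.append(_lrelu(down(feats[-1])))
        offsets = None
        aligned = None
        for level in range(self.levels - 1, -1, -1):
            f = feats[level]
            if offsets is None:
                inp = f
            else:
                up_off = ag.mul(ag.upsample_nearest2x(offsets), 2.0)
                inp = ag.concat([f, up_off], axis=1)
            offsets = self.offset_heads[level](inp)
            a = _lrelu(self.deforms[level](f, offsets))
            if aligned is not None:
                a = _lrelu(self.merges[level](ag.concat([a, ag.upsample_nearest2x(aligned)],
                                                        axis=1)))
            aligned = a
        final_off = self.refine_head(aligned)
        return _lrelu(self.refine(aligned, final_off))


class Generator(Module):
    """The full restoration network (see module docstring)."""

    def __init__(self, cfg: GeneratorConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        nf, gc, beta = cfg.base_feats, cfg.growth, cfg.residual_scale
        self.conv_first = Conv2d(cfg.in_channels, nf, 3, rng=rng, init_scale=0.1)
        self.sapcd = SAPCD(nf, cfg.pyramid_levels, cfg.deform_groups, rng) \
            if cfg.use_sapcd else None
        self.blocks = [RRDAB(nf, gc, beta, rng) for _ in range(cfg.n_rrdab)]
        self.trunk_conv = Conv2d(nf, nf, 3, rng=rng, init_scale=0.1)
        self.up1 = Conv2d(nf, nf, 3, rng=rng, init_scale=0.1)
        self.up2 = Conv2d(nf, nf, 3, rng=rng, init_scale=0.1)
        self.conv_hr = Conv2d(nf, nf, 3, rng=rng, init_scale=0.1)
        self.conv_last = Conv2d(nf, cfg.in_channels, 3, rng=rng, init_scale=0.1)

    def forward(self, x) -> Tensor:
        fea = self.conv_first(x)
        if self.sapcd is not None:
            fea = self.sapcd(fea)
        t = fea
        for block in self.blocks:
            t = block(t)
        fea = ag.add(fea, self.trunk_conv(t))
        fea = _lrelu(self.up1(ag.upsample_nearest2x(fea)))
        fea = _lrelu(self.up2(ag.upsample_nearest2x(fea)))
        return self.conv_last(_lrelu(self.conv_hr(fea)))


def build_generator(cfg: GeneratorConfig) -> Generator:
    return Generator(cfg)


def save_checkpoint(model: Generator, path) -> str:
    """Serialise parameters with the architecture config embedded."""
    import json
    from dataclasses import asdict
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez_compressed(path, config=json.dumps(asdict(model.cfg)), **arrays)
    return str(path)


def load_checkpoint(path) -> Generator:
    import json
    with np.load(path, allow_pickle=False) as data:
        cfg = GeneratorConfig(**json.loads(str(data["config"])))
        model = Generator(cfg)
        arrays = [data[f"p{i}"] for i in range(len(model.parameters()))]
    model.load_state_arrays(arrays)
    return model


def generate(image: np.ndarray, model: Generator) -> np.ndarray:
    """Restore a (H, W) or (H, W, C) image; channels are processed as
    independent modalities and re-merged.  Output is 4x larger, in [0, 1]."""
    arr = np.asarray(image, dtype=np.float32)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError("expected a (H, W) or (H, W, C) image")
    if arr.shape[2] > 3:
        raise ValueError("at most 3 modality channels are supported")
    with ag.no_grad():
        batch = arr.transpose(2, 0, 1)[:, None]  # channels as batch
        out = model(Tensor(batch)).data
    out = np.clip(out[:, 0].transpose(1, 2, 0), 0.0, 1.0)
    return out[:, :, 0] if squeeze else out
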