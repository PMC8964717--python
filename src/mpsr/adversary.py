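"""Adversarial and perceptual objectives for the restoration GAN.

The discriminator is a strided convolutional classifier whose every weight is
spectrally normalised (divided by its largest singular value, estimated by
persistent power iteration), bounding its Lipschitz constant and stabilising
adversarial training.  The adversarial loss uses the relativistic-average
formulation: the discriminator rates how much more realistic a real crop is
than the average fake crop, and vice versa; a non-saturating standard GAN
variant is available as a configuration option.

The perceptual term is the mean absolute distance between deep feature maps
of a fixed, frozen convolutional feature extractor with seeded random
weights; the generator objective combines pixel L1, perceptual and
adversarial terms with weights (1, 0.1, 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import Module, SNConv2d, SNLinear, Conv2d


@dataclass
class LossWeights:
    """Composite generator objective weights: pixel L1 weight, perceptual
    weight (lambda_1 = 0.1) and adversarial weight (lambda_2 = 0.05)."""

    w_pixel: float = 1.0
    w_percep: float = 0.1
    w_gan: float = 0.05

    def validate(self):
        if min(self.w_pixel, self.w_percep, self.w_gan) < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class LossReport:
    pixel: float
    perceptual: float
    adversarial_g: float
    total: float
    adversarial_d: float = float("nan")


class Discriminator(Module):
    """Spectral-normalised strided conv stack -> dense head -> single logit.

    Four stride-2 stages (input size must be divisible by 16); channel width
    doubles every other layer starting from ``base_feats``.
    """

    def __init__(self, input_size: int = 256, base_feats: int = 64,
                 in_channels: int = 1, seed: int = 0):
        if input_size % 16:
            raise ValueError("discriminator input size must be divisible by 16")
        rng = np.random.default_rng(seed)
        b = base_feats
        self.input_size = input_size
        widths = [(in_channels, b, 1), (b, b, 2),
                  (b, 2 * b, 1), (2 * b, 2 * b, 2),
                  (2 * b, 4 * b, 1), (4 * b, 4 * b, 2),
                  (4 * b, 8 * b, 1), (8 * b, 8 * b, 2)]
        self.convs = [SNConv2d(ci, co, 3, stride=s, rng=rng) for ci, co, s in widths]
        side = input_size // 16
        self.fc1 = SNLinear(8 * b * side * side, 100, rng=rng)
        self.fc2 = SNLinear(100, 1, rng=rng)

    def forward(self, x) -> Tensor:
        t = x
        for conv in self.convs:
            t = ag.leaky_relu(conv(t), 0.2)
        t = ag.reshape(t, (t.shape[0], -1))
        t = ag.leaky_relu(self.fc1(t), 0.2)
        return self.fc2(t)


def build_discriminator(input_size: int = 256, base_feats: int = 64,
                        seed: int = 0) -> Discriminator:
    return Discriminator(input_size=input_size, base_feats=base_feats, seed=seed)


class FeatureExtractor(Module):
    """Frozen random-feature convolutional extractor for the perceptual loss.

    A fixed, seeded stack of strided convolutions with leaky activations;
    its weights are never trained.  Single-channel inputs are replicated to
    the three channels the extractor expects.  Distances in this feature
    space form a pseudometric (non-negative, zero at identity, symmetric).
    """

    def __init__(self, seed: int = 0, width: int = 32):
        rng = np.random.default_rng(seed)
        w = width
        self.convs = [Conv2d(3, w, 3, stride=2, rng=rng),
                      Conv2d(w, 2 * w, 3, stride=2, rng=rng),
                      Conv2d(2 * w, 4 * w, 3, stride=2, rng=rng),
                      Conv2d(4 * w, 4 * w, 3, stride=1, rng=rng)]
        for c in self.convs:
            c.weight.requires_grad = False
            c.bias.requires_grad = False

    def forward(self, x) -> Tensor:
        if x.shape[1] == 1:
            x = ag.concat([x, x, x], axis=1)
        t = x
        for conv in self.convs[:-1]:
            t = ag.leaky_relu(conv(t), 0.2)
        return self.convs[-1](t)  # pre-activation deep features


def perceptual_loss(sr, gt, extractor: FeatureExtractor) -> Tensor:
    """Mean absolute difference between deep feature maps of sr and gt."""
    sr, gt = ag.as_tensor(sr), ag.as_tensor(gt)
    if sr.shape != gt.shape:
        raise ValueError(f"shape mismatch: {sr.shape} vs {gt.shape}")
    return ag.mean(ag.absolute(ag.sub(extractor(sr), extractor(gt))))


def pixel_l1(sr, gt) -> Tensor:
    sr, gt = ag.as_tensor(sr), ag.as_tensor(gt)
    if sr.shape != gt.shape:
        raise ValueError(f"shape mismatch: {sr.shape} vs {gt.shape}")
    return ag.mean(ag.absolute(ag.sub(sr, gt)))


def adversarial_losses(d_real, d_fake, mode: str = "relativistic"):
    """Generator and discriminator adversarial terms from raw logits.

    relativistic (default): binary cross-entropy on relativistic-average
    logits, D(real) - mean D(fake) and D(fake) - mean D(real).
    standard: non-saturating GAN.
    Returns (g_term, d_term) as scalar Tensors.
    """
    d_real, d_fake = ag.as_tensor(d_real), ag.as_tensor(d_fake)
    if d_real.size == 0 or d_fake.size == 0:
        raise ValueError("empty logit batch")
    if d_real.size != d_fake.size:
        raise ValueError("real/fake batch sizes differ")
    if mode == "relativistic":
        mr = ag.mean(d_real)
        mf = ag.mean(d_fake)
        rel_r = ag.sub(d_real, mf)   # how much more real than avg fake
        rel_f = ag.sub(d_fake, mr)
        # BCE(logit, 1) = softplus(-logit); BCE(logit, 0) = softplus(logit)
        d_term = ag.add(ag.mean(ag.softplus(ag.mul(rel_r, -1.0))),
                        ag.mean(ag.softplus(rel_f)))
        g_term = ag.add(ag.mean(ag.softplus(rel_r)),
                        ag.mean(ag.softplus(ag.mul(rel_f, -1.0))))
        return g_term, d_term
    if mode == "standard":
        d_term = ag.add(ag.mean(ag.softplus(ag.mul(d_real, -1.0))),
                        ag.mean(ag.softplus(d_fake)))
        g_term = ag.mean(ag.softplus(ag.mul(d_fake, -1.0)))
        return g_term, d_term
    raise ValueError(f"unknown adversarial mode {mode!r}")


def total_generator_loss(sr, gt, d_real, d_fake, weights: LossWeights,
                         extractor: FeatureExtractor | None = None,
                         mode: str = "relativistic"):
    """Composite generator objective.

    Returns (loss_tensor, LossReport); the report satisfies
    total == w_pixel*pixel + w_percep*perceptual + w_gan*adversarial_g
    exactly (the total is assembled from exactly those scalars).
    """
    weights.validate()
    terms = []
    pix = pixel_l1(sr, gt)
    terms.append(ag.mul(pix, weights.w_pixel))
    if weights.w_percep > 0:
        if extractor is None:
            raise ValueError("perceptual weight > 0 requires a feature extractor")
        per = perceptual_loss(sr, gt, extractor)
        terms.append(ag.mul(per, weights.w_percep))
        per_val = float(per.data)
    else:
        per_val = 0.0
    if weights.w_gan > 0:
        g_term, d_term = adversarial_losses(d_real, d_fake, mode=mode)
        terms.append(ag.mul(g_term, weights.w_gan))
        g_val, d_val = float(g_term.data), float(d_term.data)
    else:
        g_val, d_val = 0.0, float("nan")
    total = terms[0]
    for t in terms[1:]:
        total = ag.add(total, t)
    report = LossReport(
        pixel=float(pix.data), perceptual=per_val, adversarial_g=g_val,
        total=weights.w_pixel * float(pix.data) + weights.w_percep * per_val
              + weights.w_gan * g_val,
        adversarial_d=d_val)
    return total, report
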