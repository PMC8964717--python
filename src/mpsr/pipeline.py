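"""Dataset preparation, GAN training loop, and tiled large-image inference.

Training pairs are cut from preregistered acquisitions: the low-resolution
input is trimmed by 16 px per side (64 px on the ground truth, keeping the
4x alignment), tiled at 128x128 with stride 64, and each tile is paired with
the 512x512 ground-truth region at 4x its origin.  Batches are random
aligned crops (input 64 -> GT 256 by default) with one flip/rotation
augmentation applied identically to both members.

Inference splits a large image into a 4x4 grid of disjoint tiles, restores
each tile per channel, and reassembles the mosaic at 4x the input origins;
a seam metric (boundary-gradient excess) quantifies stitching artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adversary import (Discriminator, FeatureExtractor, LossWeights,
                        adversarial_losses, total_generator_loss)
from .generator import Generator
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import Adam


@dataclass
class TilePlan:
    tile_origins: list          # [(row, col), ...]
    tile_size: tuple            # (h, w)
    stride: tuple               # (h, w)
    grid: tuple                 # (rows, cols)
    blend: str = "none"         # "none" | "feather"


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    The full-scale protocol uses batch 8, 64->256 crops and 400k iterations;
    the CPU-scale presets in the test-suite use a few hundred.
    """

    batch_size: int = 8
    input_crop: int = 64
    gt_crop: int = 256
    iterations: int = 400_000
    warmup_iterations: int = 0   # pixel-only phase before adversarial terms
    learning_rate: float = 1e-4
    finetune_lr_factor: float = 0.2   # generator lr multiplier after warmup
    d_lr_factor: float = 2.0          # discriminator lr relative to generator
    lr_milestones: tuple = ()
    betas: tuple = (0.9, 0.99)
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    adversarial_mode: str = "relativistic"
    log_every: int = 1

    def validate(self):
        if self.gt_crop != 4 * self.input_crop:
            raise ValueError("gt_crop must equal 4 * input_crop")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def prepare_training_tiles(input_img: np.ndarray, gt_img: np.ndarray,
                           tile: int = 128, stride: int = 64, trim: int = 16):
    """Cut aligned (input, GT) tile pairs from a preregistered pair.

    Input tiles are `tile` x `tile` at the given stride after trimming
    `trim` px per side; each GT tile is the (4*tile) region at 4x the input
    origin.  Tiles whose GT region would exceed bounds are dropped.
    Returns a list of (input_tile, gt_tile, origin) with 2-D float32 tiles.
    """
    inp = np.asarray(input_img, dtype=np.float32)
    gt = np.asarray(gt_img, dtype=np.float32)
    if inp.ndim != 2 or gt.ndim != 2:
        raise ValueError("prepare_training_tiles expects single-channel images")
    if gt.shape != (4 * inp.shape[0], 4 * inp.shape[1]):
        raise ValueError("GT dims must be 4x input dims")
    h, w = inp.shape
    pairs = []
    for r in range(trim, h - trim - tile + 1, stride):
        for c in range(trim, w - trim - tile + 1, stride):
            gr, gc = 4 * r, 4 * c
            if gr + 4 * tile > gt.shape[0] or gc + 4 * tile > gt.shape[1]:
                continue
            pairs.append((inp[r:r + tile, c:c + tile],
                          gt[gr:gr + 4 * tile, gc:gc + 4 * tile],
                          (r, c)))
    return pairs


def expected_tile_count(side: int, tile: int = 128, stride: int = 64,
                        trim: int = 16) -> int:
    """Stride-count formula for one axis: floor((side - 2*trim - tile)/stride) + 1."""
    usable = side - 2 * trim
    if usable < tile:
        return 0
    return (usable - tile) // stride + 1


_AUGMENTATIONS = ("none", "fliplr", "flipud", "rot90", "rot180", "rot270")


def _augment(arr: np.ndarray, op: str) -> np.ndarray:
    if op == "none":
        return arr
    if op == "fliplr":
        return arr[:, ::-1]
    if op == "flipud":
        return arr[::-1, :]
    if op == "rot90":
        return np.rot90(arr, 1)
    if op == "rot180":
        return np.rot90(arr, 2)
    if op == "rot270":
        return np.rot90(arr, 3)
    raise ValueError(op)


def sample_training_batch(tiles, cfg: TrainConfig, rng: np.random.Generator):
    """Draw a batch of aligned random crops with a random flip/rotation.

    Returns (input_batch, gt_batch) as (B, 1, c, c) and (B, 1, 4c, 4c)
    float32 arrays.
    """
    if not tiles:
        raise ValueError("empty tile list")
    ci, cg = cfg.input_crop, cfg.gt_crop
    xs = np.empty((cfg.batch_size, 1, ci, ci), dtype=np.float32)
    ys = np.empty((cfg.batch_size, 1, cg, cg), dtype=np.float32)
    for b in range(cfg.batch_size):
        inp, gt, _ = tiles[rng.integers(len(tiles))]
        if inp.shape[0] < ci or inp.shape[1] < ci:
            raise ValueError("tile smaller than requested crop")
        r = int(rng.integers(inp.shape[0] - ci + 1))
        c = int(rng.integers(inp.shape[1] - ci + 1))
        op = _AUGMENTATIONS[rng.integers(len(_AUGMENTATIONS))]
        xs[b, 0] = _augment(inp[r:r + ci, c:c + ci], op)
        ys[b, 0] = _augment(gt[4 * r:4 * r + cg, 4 * c:4 * c + cg], op)
    return xs, ys


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class TrainingDiverged(RuntimeError):
    def __init__(self, iteration, report):
        super().__init__(f"non-finite loss at iteration {iteration}: {report}")
        self.iteration = iteration
        self.report = report


def train(tiles, generator: Generator, discriminator: Discriminator | None,
          cfg: TrainConfig, extractor: FeatureExtractor | None = None,
          callback=None):
    """Alternating GAN optimisation (one discriminator step, one generator
    step per iteration) with Adam; fully reproducible under cfg.seed.

    With zero perceptual and adversarial weights this reduces to plain L1
    training and no discriminator is touched.  Returns (generator, history)
    where history is a list of per-iteration loss dicts.
    """
    cfg.validate()
    cfg.loss_weights.validate()
    rng = np.random.default_rng(cfg.seed)
    use_gan = cfg.loss_weights.w_gan > 0
    if use_gan and discriminator is None:
        raise ValueError("adversarial weight > 0 requires a discriminator")
    if cfg.loss_weights.w_percep > 0 and extractor is None:
        extractor = FeatureExtractor(seed=0)
    opt_g = Adam(generator.parameters(), lr=cfg.learning_rate, betas=cfg.betas)
    opt_d = Adam(discriminator.parameters(),
                 lr=cfg.learning_rate * cfg.d_lr_factor,
                 betas=cfg.betas) if use_gan else None
    milestones = set(cfg.lr_milestones)
    warm_weights = LossWeights(cfg.loss_weights.w_pixel, 0.0, 0.0)
    history = []
    for it in range(cfg.iterations):
        if it in milestones:
            opt_g.lr *= 0.5
            if opt_d is not None:
                opt_d.lr *= 0.5
        warm = it < cfg.warmup_iterations
        if cfg.warmup_iterations and it == cfg.warmup_iterations:
            opt_g.lr *= cfg.finetune_lr_factor
        xb, yb = sample_training_batch(tiles, cfg, rng)
        x = Tensor(xb)
        y = Tensor(yb)

        d_loss_val = float("nan")
        if use_gan and not warm:
            # discriminator step on detached generator output
            sr_det = generator(x).detach()
            logit_real = discriminator(y)
            logit_fake = discriminator(sr_det)
            _, d_loss = adversarial_losses(logit_real, logit_fake,
                                           mode=cfg.adversarial_mode)
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()
            d_loss_val = float(d_loss.data)

        # generator step
        sr = generator(x)
        if use_gan and not warm:
            logit_real = discriminator(y).detach()
            logit_fake = discriminator(sr)
        else:
            logit_real = logit_fake = Tensor(np.zeros(cfg.batch_size, np.float32))
        weights = warm_weights if warm else cfg.loss_weights
        loss, report = total_generator_loss(sr, y, logit_real, logit_fake,
                                            weights, extractor,
                                            mode=cfg.adversarial_mode)
        opt_g.zero_grad()
        if opt_d is not None:
            opt_d.zero_grad()
        loss.backward()
        opt_g.step()

        rec = {"iteration": it, "pixel": report.pixel,
               "perceptual": report.perceptual,
               "adversarial_g": report.adversarial_g,
               "adversarial_d": d_loss_val, "total": report.total}
        if not np.isfinite(report.total):
            raise TrainingDiverged(it, rec)
        if it % cfg.log_every == 0:
            history.append(rec)
        if callback is not None:
            callback(it, rec)
    return generator, history


def history_to_csv(history, path):
    import csv
    if not history:
        cols = ["iteration", "pixel", "perceptual", "adversarial_g",
                "adversarial_d", "total"]
    else:
        cols = list(history[0].keys())
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        for row in history:
            w.writerow(row)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def plan_inference_tiles(image_dims, grid=(4, 4), blend: str = "none") -> TilePlan:
    """Disjoint equal tiles covering the image exactly (default 4x4 grid)."""
    h, w = image_dims
    gr, gc = grid
    if h % gr or w % gc:
        raise ValueError(
            f"image dims {h}x{w} not divisible by grid {gr}x{gc}; pad the "
            "image to a multiple of the grid first")
    th, tw = h // gr, w // gc
    origins = [(r * th, c * tw) for r in range(gr) for c in range(gc)]
    return TilePlan(tile_origins=origins, tile_size=(th, tw),
                    stride=(th, tw), grid=grid, blend=blend)


def coverage_mask(plan: TilePlan, image_dims) -> np.ndarray:
    """How many tiles cover each pixel (exact partition -> all ones)."""
    mask = np.zeros(image_dims, dtype=np.int32)
    th, tw = plan.tile_size
    for r, c in plan.tile_origins:
        mask[r:r + th, c:c + tw] += 1
    return mask


def seam_metric(image: np.ndarray, plan: TilePlan, scale: int = 4) -> float:
    """Mean absolute gradient across tile boundaries minus its off-boundary
    counterpart; ~0 when stitching introduces no discontinuities.

    The off-boundary reference uses only rows/columns at the same phase
    modulo `scale`, so the block structure of x4-upsampled images does not
    bias the comparison.
    """
    img = image.mean(axis=2) if image.ndim == 3 else image
    th, tw = plan.tile_size[0] * scale, plan.tile_size[1] * scale
    gr, gc = plan.grid
    gy = np.abs(np.diff(img, axis=0))
    gx = np.abs(np.diff(img, axis=1))
    rows = np.array([r * th - 1 for r in range(1, gr)], dtype=int)
    cols = np.array([c * tw - 1 for c in range(1, gc)], dtype=int)
    on = []
    if rows.size:
        on.append(gy[rows, :].ravel())
    if cols.size:
        on.append(gx[:, cols].ravel())
    if not on:
        return 0.0
    on_val = float(np.concatenate(on).mean())
    phase = (th - 1) % scale
    same_phase_rows = np.setdiff1d(np.arange(phase, gy.shape[0], scale), rows)
    same_phase_cols = np.setdiff1d(np.arange((tw - 1) % scale, gx.shape[1], scale),
                                   cols)
    off = []
    if same_phase_rows.size:
        off.append(gy[same_phase_rows, :].ravel())
    if same_phase_cols.size:
        off.append(gx[:, same_phase_cols].ravel())
    off_val = float(np.concatenate(off).mean()) if off else 0.0
    return on_val - off_val


def predict_large(image: np.ndarray, model, plan: TilePlan | None = None,
                  return_seam_metric: bool = False):
    """Tiled restoration of a large (H, W) or (H, W, C) image.

    Channels are treated as independent modalities and batched together per
    tile; each tile is restored independently and placed at 4x its origin.
    """
    arr = np.asarray(image, dtype=np.float32)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[:, :, None]
    if arr.shape[2] > 3:
        raise ValueError("at most 3 modality channels")
    if plan is None:
        plan = plan_inference_tiles(arr.shape[:2])
    th, tw = plan.tile_size
    scale = 4
    out = np.empty((arr.shape[0] * scale, arr.shape[1] * scale, arr.shape[2]),
                   dtype=np.float32)
    with ag.no_grad():
        for r, c in plan.tile_origins:
            tile = arr[r:r + th, c:c + tw]
            batch = tile.transpose(2, 0, 1)[:, None]  # (C,1,h,w)
            pred = model(Tensor(batch)).data
            pred = np.clip(pred[:, 0].transpose(1, 2, 0), 0.0, 1.0)
            out[r * scale:(r + th) * scale, c * scale:(c + tw) * scale] = pred
    result = out[:, :, 0] if squeeze else out
    if return_seam_metric:
        return result, seam_metric(result, plan, scale)
    return result


def bicubic_x4(image: np.ndarray) -> np.ndarray:
    """Bicubic x4 upsampling baseline, clipped to [0, 1]."""
    from skimage.transform import resize
    arr = np.asarray(image, dtype=np.float32)
    out_shape = (arr.shape[0] * 4, arr.shape[1] * 4) + arr.shape[2:]
    up = resize(arr, out_shape, order=3, anti_aliasing=False)
    return np.clip(up, 0.0, 1.0).astype(np.float32)
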