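"""Synthetic paired acquisitions: clean multimodal phantoms and their
realistic fast-scan degradations.

No public dataset of paired resonant-scan / galvo-scan multiphoton images is
available, so every downstream stage (registration, training, metrology) is
exercised on synthetic phantoms whose three channels emulate the morphologies
seen in label-free nonlinear imaging: curvilinear fibres (collagen-like SHG
structures), elliptical blobs (cells, follicles) and granular speckle
(autofluorescence texture).

The degradation model mirrors the physics of a fast galvo-resonant
acquisition, applied in causal order:

    optics blur -> scanner-geometry misalignment -> x4 undersampling ->
    Poisson shot noise -> Gaussian read noise -> multiplicative row-gain
    scanning fringes (SFA) -> additive stitching-lattice offsets (SLA) ->
    clip to [0, 1]

Default noise amplitudes follow the 8-bit exemplars of resonant-scan tissue
imaging: read-noise STD ~20/255 against a mean foreground signal of ~62/255.
All randomness flows from one integer seed; identical configurations are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .registration import PlanarTransform, warp

CHANNEL_KINDS = ("fibers", "blobs", "granular")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Ground-truth phantom description.

    shape_gt: (height, width) of the clean image, divisible by 16
        (downsample factor x inference grid).
    channels: channel kinds, subset of {"fibers", "blobs", "granular"}.
    structure_density: structures per megapixel, per channel.
    intensity_range: (background_level, peak_level) in [0, 1].
    """

    shape_gt: tuple[int, int] = (512, 512)
    channels: tuple[str, ...] = ("fibers", "blobs", "granular")
    structure_density: float = 350.0
    intensity_range: tuple[float, float] = (0.02, 0.9)
    seed: int = 0

    def validate(self, divisor: int = 16):
        h, w = self.shape_gt
        if h % divisor or w % divisor:
            raise ValueError(f"phantom dims must be divisible by {divisor}, got {h}x{w}")
        for c in self.channels:
            if c not in CHANNEL_KINDS:
                raise ValueError(f"unknown channel kind {c!r}")
        if len(self.channels) > 3:
            raise ValueError("at most 3 channels")
        lo, hi = self.intensity_range
        if not 0 <= lo < hi <= 1:
            raise ValueError("require 0 <= background_level < peak_level <= 1")
        if self.structure_density < 0:
            raise ValueError("structure_density must be >= 0")


@dataclass
class DegradationConfig:
    """Parameters of the fast-scan degradation pipeline (see module docs)."""

    psf_fwhm_gt_px: float = 2.0
    psf_fwhm_input_px: float = 6.0
    downsample_factor: int = 4
    read_noise_std: float = 20.0 / 255.0
    photon_gain: float = 200.0
    sfa_amplitude: float = 0.25
    sfa_period_rows: float = 16.0
    sla_field_grid: tuple[int, int] = (16, 16)
    sla_overlap: float = 0.5
    sla_seam_amplitude: float = 0.03
    misalign_max_shift_px: float = 20.0
    misalign_max_rot_deg: float = 1.0
    misalign_max_scale: float = 0.01
    seed: int = 0

    def validate(self):
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if not 0 <= self.sla_overlap < 1:
            raise ValueError("sla_overlap must lie in [0, 1)")
        for name in ("read_noise_std", "sfa_amplitude", "sla_seam_amplitude",
                     "psf_fwhm_gt_px", "psf_fwhm_input_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.photon_gain < 0:
            raise ValueError("photon_gain must be >= 0")
        if not 0 <= self.misalign_max_shift_px <= 200:
            raise ValueError("misalign_max_shift_px must lie in [0, 200]")
        if self.sfa_amplitude >= 1:
            raise ValueError("sfa_amplitude must be < 1")


@dataclass
class PairedAcquisition:
    """A degraded fast-scan image with its clean slow-scan counterpart."""

    input_image: np.ndarray          # (h, w, C) float32 in [0,1]
    gt_image: np.ndarray             # (4h, 4w, C) float32 in [0,1]
    true_transform: PlanarTransform  # misalignment applied at GT scale
    signal_mask: np.ndarray          # bool, GT scale
    background_mask: np.ndarray      # bool, GT scale
    config: DegradationConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def _fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _draw_fibers(shape, n, rng):
    """Smooth curvilinear structures: quadratic Bezier polylines with a
    Gaussian cross-profile.  Returns (image, list of control points)."""
    h, w = shape
    img = np.zeros(shape, dtype=np.float32)
    placements = []
    for _ in range(n):
        p0 = rng.uniform([0, 0], [h, w])
        span = rng.uniform(0.15, 0.5) * min(h, w)
        ang = rng.uniform(0, 2 * np.pi)
        p2 = p0 + span * np.array([np.sin(ang), np.cos(ang)])
        p1 = 0.5 * (p0 + p2) + rng.normal(0, 0.15 * span, 2)
        t = np.linspace(0, 1, max(8, int(2 * span)))[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2
        ij = np.round(pts).astype(int)
        keep = (ij[:, 0] >= 0) & (ij[:, 0] < h) & (ij[:, 1] >= 0) & (ij[:, 1] < w)
        ij = ij[keep]
        if len(ij) == 0:
            continue
        amp = rng.uniform(0.6, 1.0)
        img[ij[:, 0], ij[:, 1]] = np.maximum(img[ij[:, 0], ij[:, 1]], amp)
        placements.append(pts)
    width = 1.8
    img = gaussian_filter(img, width)
    peak = img.max()
    if peak > 0:
        img /= peak
    return img, placements


def _draw_blobs(shape, n, rng):
    """Elliptical cell-like blobs with soft edges."""
    h, w = shape
    img = np.zeros(shape, dtype=np.float32)
    placements = []
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    for _ in range(n):
        cy, cx = rng.uniform([0, 0], [h, w])
        a = rng.uniform(4, 14)
        b = a * rng.uniform(0.5, 1.0)
        th = rng.uniform(0, np.pi)
        amp = rng.uniform(0.5, 1.0)
        # evaluate only in a local window for speed
        r = int(3 * a) + 2
        y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r)
        x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r)
        if y0 >= y1 or x0 >= x1:
            continue
        dy = yy[y0:y1, x0:x1] - cy
        dx = xx[y0:y1, x0:x1] - cx
        u = dy * np.cos(th) + dx * np.sin(th)
        v = -dy * np.sin(th) + dx * np.cos(th)
        e = (u / a) ** 2 + (v / b) ** 2
        patch = amp * np.exp(-np.maximum(e - 1, 0) * 6) * (e < 4)
        np.maximum(img[y0:y1, x0:x1], patch.astype(np.float32),
                   out=img[y0:y1, x0:x1])
        placements.append((cy, cx, a, b, th))
    return img, placements


def _draw_granular(shape, n, rng):
    """Speckled texture: seeded point process smoothed at a small scale."""
    h, w = shape
    img = np.zeros(shape, dtype=np.float32)
    n_pts = max(n * 60, 60) if n else 0
    placements = []
    if n_pts:
        ys = rng.integers(0, h, n_pts)
        xs = rng.integers(0, w, n_pts)
        amps = rng.uniform(0.3, 1.0, n_pts).astype(np.float32)
        np.maximum.at(img, (ys, xs), amps)
        placements = list(zip(ys.tolist(), xs.tolist()))
        img = gaussian_filter(img, 1.0)
        peak = img.max()
        if peak > 0:
            img /= peak
    return img, placements


_DRAWERS = {"fibers": _draw_fibers, "blobs": _draw_blobs, "granular": _draw_granular}


def generate_phantom(spec: PhantomSpec, return_log: bool = False):
    """Render a clean multimodal phantom in [0, 1].

    With ``return_log=True`` also returns, per channel, the list of placed
    structures (an independent record used to verify structure counts).
    """
    spec.validate()
    h, w = spec.shape_gt
    lo, hi = spec.intensity_range
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.structure_density * h * w / 1e6))
    out = np.empty((h, w, len(spec.channels)), dtype=np.float32)
    log = {}
    for ci, kind in enumerate(spec.channels):
        raster, placements = _DRAWERS[kind]((h, w), n, rng)
        out[:, :, ci] = lo + (hi - lo) * raster
        log[kind] = placements
    if return_log:
        return out, log
    return out


# ---------------------------------------------------------------------------
# degradation stages
# ---------------------------------------------------------------------------

def _smooth_periodic_profile(n_rows, period, rng, jitter=0.1):
    """Zero-ish-mean periodic row profile: unit sinusoid with a slowly varying
    seeded phase jitter."""
    rows = np.arange(n_rows, dtype=np.float64)
    phase0 = rng.uniform(0, 2 * np.pi)
    raw = rng.standard_normal(n_rows)
    wobble = gaussian_filter(raw, max(2.0, period)) * jitter * 10
    return np.sin(2 * np.pi * rows / period + phase0 + wobble).astype(np.float32)


def add_scan_fringes(image: np.ndarray, amplitude: float, period_rows: float,
                     seed: int = 0) -> np.ndarray:
    """Multiplicative row-gain fringes: each row scaled by 1 + a*s(row)."""
    if amplitude >= 1:
        raise ValueError("fringe amplitude must be < 1")
    if amplitude == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    s = _smooth_periodic_profile(image.shape[0], period_rows, rng)
    gain = (1.0 + amplitude * s).astype(np.float32)
    shape = (-1,) + (1,) * (image.ndim - 1)
    return image * gain.reshape(shape)


def _field_windows(n: int, grid: int, overlap: float):
    """1-D blend windows for `grid` stitched fields spanning n pixels.

    Returns (starts, length, window) where window is a feathered weight
    profile; with zero overlap the windows are exact disjoint blocks.
    """
    if n % grid:
        raise ValueError(f"field grid {grid} does not divide image extent {n}")
    stride = n // grid
    length = min(n, int(round(stride * (1 + overlap))))
    ramp = length - stride  # feather width on each interior side
    win = np.ones(length, dtype=np.float32)
    if ramp > 0:
        edge = (np.arange(1, ramp + 1) / (ramp + 1)).astype(np.float32)
        win[:ramp] = edge
        win[-ramp:] = edge[::-1]
    starts = [min(i * stride, n - length) for i in range(grid)]
    return starts, length, win


def add_stitch_lattice(image: np.ndarray, field_grid=(16, 16), overlap: float = 0.5,
                       seam_amplitude: float = 0.03, seed: int = 0,
                       offsets: np.ndarray | None = None) -> np.ndarray:
    """Additive per-field brightness offsets blended at the field lattice.

    Each scan field receives a seeded brightness offset (STD
    ``seam_amplitude``); fields are feather-blended with the given overlap
    fraction, leaving a lattice at the field stride.  ``offsets`` may supply
    an explicit (rows, cols) offset table instead of the seeded draw.
    """
    if seam_amplitude == 0 and offsets is None:
        return image.copy()
    h, w = image.shape[:2]
    gr, gc = field_grid
    rng = np.random.default_rng(seed)
    if offsets is None:
        offsets = rng.normal(0.0, seam_amplitude, (gr, gc)).astype(np.float32)
    else:
        offsets = np.asarray(offsets, dtype=np.float32)
        if offsets.shape != (gr, gc):
            raise ValueError("offsets table must match field_grid")
    ys, ly, wy = _field_windows(h, gr, overlap)
    xs, lx, wx = _field_windows(w, gc, overlap)
    acc = np.zeros((h, w), dtype=np.float32)
    den = np.zeros((h, w), dtype=np.float32)
    w2d = wy[:, None] * wx[None, :]
    for i, y0 in enumerate(ys):
        for j, x0 in enumerate(xs):
            acc[y0:y0 + ly, x0:x0 + lx] += w2d * offsets[i, j]
            den[y0:y0 + ly, x0:x0 + lx] += w2d
    lattice = acc / den
    if image.ndim == 3:
        lattice = lattice[:, :, None]
    return image + lattice


def _downsample_area(img: np.ndarray, f: int) -> np.ndarray:
    """Box-filter (integrating-detector) downsampling by integer factor."""
    if f == 1:
        return img.copy()
    h, w = img.shape[:2]
    if h % f or w % f:
        raise ValueError(f"dims {h}x{w} not divisible by downsample factor {f}")
    if img.ndim == 2:
        return img.reshape(h // f, f, w // f, f).mean(axis=(1, 3))
    return img.reshape(h // f, f, w // f, f, -1).mean(axis=(1, 3))


def _random_misalignment(cfg: DegradationConfig, shape, rng) -> PlanarTransform:
    """Random similarity misalignment (shift, rotation, scale) about centre."""
    shift_xy = rng.uniform(-cfg.misalign_max_shift_px, cfg.misalign_max_shift_px, 2)
    rot = rng.uniform(-cfg.misalign_max_rot_deg, cfg.misalign_max_rot_deg)
    scale = 1.0 + rng.uniform(-cfg.misalign_max_scale, cfg.misalign_max_scale)
    h, w = shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    return PlanarTransform.from_similarity(shift_xy=shift_xy, rot_deg=rot,
                                           scale=scale, center_xy=center)


def _blur(img: np.ndarray, fwhm: float) -> np.ndarray:
    if fwhm <= 0:
        return img.copy()
    sigma = _fwhm_to_sigma(fwhm)
    if img.ndim == 2:
        return gaussian_filter(img, sigma)
    return gaussian_filter(img, (sigma, sigma, 0))


def degrade(gt: np.ndarray, cfg: DegradationConfig,
            misalign: PlanarTransform | None = None) -> PairedAcquisition:
    """Apply the full fast-scan degradation pipeline to a clean phantom.

    With the identity configuration (factor 1, zero amplitudes, equal PSFs,
    zero misalignment) the input equals the ground truth bit-for-bit.
    ``misalign`` overrides the seeded random misalignment with an explicit
    transform (e.g. the fixed geometric offset of a two-scanner system).
    """
    cfg.validate()
    gt = np.asarray(gt, dtype=np.float32)
    if gt.min() < 0 or gt.max() > 1:
        raise ValueError("ground-truth image must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    squeeze = gt.ndim == 2
    work = gt[:, :, None] if squeeze else gt

    identity_geom = (cfg.misalign_max_shift_px == 0 and cfg.misalign_max_rot_deg == 0
                     and cfg.misalign_max_scale == 0)

    # 1. optics blur of the fast-scan arm
    x = _blur(work, cfg.psf_fwhm_input_px) if cfg.psf_fwhm_input_px else work.copy()

    # 2. scanner-geometry misalignment (recorded)
    tform = misalign if misalign is not None \
        else _random_misalignment(cfg, work.shape[:2], rng)
    if misalign is not None or not identity_geom:
        x = np.stack([warp(x[:, :, c], tform, x.shape[:2]) for c in range(x.shape[2])],
                     axis=2)
    else:
        tform = PlanarTransform(matrix=np.eye(3))

    # 3. x4 undersampling (area average emulating integrating detection)
    x = _downsample_area(x, cfg.downsample_factor).astype(np.float32)

    # 4. Poisson shot noise
    if cfg.photon_gain > 0:
        x = (rng.poisson(np.clip(x, 0, None) * cfg.photon_gain) /
             cfg.photon_gain).astype(np.float32)

    # 5. Gaussian read noise
    if cfg.read_noise_std > 0:
        x = x + rng.normal(0.0, cfg.read_noise_std, x.shape).astype(np.float32)

    # 6. scanning fringes (row gains)
    if cfg.sfa_amplitude > 0:
        x = add_scan_fringes(x, cfg.sfa_amplitude, cfg.sfa_period_rows,
                             seed=int(rng.integers(2 ** 31)))

    # 7. stitching-lattice offsets
    if cfg.sla_seam_amplitude > 0:
        x = add_stitch_lattice(x, cfg.sla_field_grid, cfg.sla_overlap,
                               cfg.sla_seam_amplitude, seed=int(rng.integers(2 ** 31)))

    # 8. clip
    x = np.clip(x, 0.0, 1.0).astype(np.float32)

    # the slow-scan arm: independently blurred at its own (smaller) PSF
    gt_out = _blur(work, cfg.psf_fwhm_gt_px).astype(np.float32) \
        if cfg.psf_fwhm_gt_px else work.copy()
    gt_out = np.clip(gt_out, 0.0, 1.0)

    sig_mask, bg_mask = derive_masks(gt_out)
    inp = x[:, :, 0] if squeeze else x
    gt_final = gt_out[:, :, 0] if squeeze else gt_out
    return PairedAcquisition(input_image=inp, gt_image=gt_final, true_transform=tform,
                             signal_mask=sig_mask, background_mask=bg_mask, config=cfg)


def derive_masks(gt: np.ndarray, signal_q: float = 0.9, background_q: float = 0.1):
    """Disjoint signal/background masks thresholded on the clean reference:
    signal = top intensity decile, background = bottom decile."""
    ref = gt.max(axis=2) if gt.ndim == 3 else gt
    lo = np.quantile(ref, background_q)
    hi = np.quantile(ref, signal_q)
    return ref >= hi, ref <= lo


def identity_config(**overrides) -> DegradationConfig:
    """A configuration under which degradation is the exact identity."""
    base = DegradationConfig(
        psf_fwhm_gt_px=0.0, psf_fwhm_input_px=0.0, downsample_factor=1,
        read_noise_std=0.0, photon_gain=0.0, sfa_amplitude=0.0,
        sla_seam_amplitude=0.0, misalign_max_shift_px=0.0,
        misalign_max_rot_deg=0.0, misalign_max_scale=0.0)
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# point grids for PSF metrology
# ---------------------------------------------------------------------------

def simulate_point_grid(n_points: int, sigma_px: float, shape=(256, 256),
                        seed: int = 0, amplitude: float = 1.0):
    """Isolated Gaussian spots of known sigma on zero background.

    Spots are laid out on a jittered lattice; a configuration that cannot
    keep centres >= 10*sigma apart is rejected.  Returns (image, centres).
    """
    h, w = shape
    img = np.zeros(shape, dtype=np.float32)
    if n_points == 0:
        return img, np.empty((0, 2))
    side = int(np.ceil(np.sqrt(n_points)))
    pitch_y, pitch_x = h / side, w / side
    min_sep = 10.0 * sigma_px
    if min(pitch_y, pitch_x) < min_sep:
        raise ValueError(
            f"{n_points} spots of sigma {sigma_px} cannot be separated by "
            f">= {min_sep:.1f} px in a {h}x{w} image")
    rng = np.random.default_rng(seed)
    jitter = max(0.0, (min(pitch_y, pitch_x) - min_sep) / 2 - 1)
    centers = []
    for idx in range(n_points):
        gy, gx = divmod(idx, side)
        cy = (gy + 0.5) * pitch_y + rng.uniform(-jitter, jitter)
        cx = (gx + 0.5) * pitch_x + rng.uniform(-jitter, jitter)
        centers.append((cy, cx))
        r = int(np.ceil(5 * sigma_px))
        y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
        x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px ** 2))
    return img, np.array(centers)
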