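# Methods

`mpsr` restores fast resonant-scan multiphoton images — noisy, fringed,
×4-undersampled and geometrically offset from their slow galvo-scan
counterparts — into denoised, ×4 super-resolved images. This note documents
the models, the synthetic study system, the numerical choices, and what the
shipped tests do and do not establish.

## The restoration model

The generator maps one modality channel (two-photon FAD autofluorescence,
second-harmonic generation, or three-photon NADH autofluorescence, processed
independently) from the low-resolution frame to a ×4 output:

1. **Shallow feature extraction** — one 3×3 convolution to `base_feats`
   channels (default 64; the CPU-scale preset used throughout the tests is
   16 features, 2 trunk blocks, 2 pyramid levels).
2. **Self-alignment (SAPCD)** — a pyramid of strided convolutions
   (`pyramid_levels`, default 3). At the coarsest level an offset field
   (2 offsets × 9 taps × `deform_groups`) is predicted *from the features
   themselves* — at inference time there is no reference frame to align to —
   and applied by a 3×3 deformable convolution. Offsets are nearest-upsampled
   (values doubled, staying in pixels of the finer grid) and concatenated as
   priors into the next finer level; a final deformable refinement runs at
   full resolution. All offset heads end in zero-initialised convolutions, so
   alignment starts as the identity: a deformable convolution with zero
   offsets is numerically a plain 3×3 convolution.
3. **RRDAB trunk** — `n_rrdab` residual-in-residual dense attention blocks.
   Each block stacks three dense sub-blocks (five 3×3 convolutions with dense
   connectivity, growth `growth`, leaky-ReLU slope 0.2, the last projection
   zero-initialised, inner residual scale β = 0.2), then a
   squeeze-and-excitation channel gate (global average pool → bottleneck,
   reduction 4 → sigmoid) followed by a spatial gate (channel mean+max maps →
   7×7 convolution → sigmoid), then the outer residual `out = x + β·attended`.
   Channel-then-spatial ordering follows the CBAM convention; the gate
   placement between the dense stack and the outer residual is this package's
   design choice.
4. **Global skip** — the trunk output (after one convolution) is added back
   to the post-alignment features.
5. **Upsampling head** — exactly two stages of nearest-neighbour ×2
   upsampling + convolution + leaky ReLU, then a reconstruction convolution
   pair. Only ×4 is supported; outputs are clipped to [0, 1] at the
   `generate`/`predict_large` boundary (training sees unclipped values).

The discriminator is a strided convolutional classifier (four stride-2
stages, width doubling from `base_feats`, dense head to a single logit) with
*every* weight spectrally normalised: one persistent power iteration per
forward estimates the largest singular value and the weight is divided by it
inside the autodiff graph, bounding the Lipschitz constant.

**Objective.** `total = w_pixel·L1 + λ₁·perceptual + λ₂·adversarial` with
`w_pixel = 1`, `λ₁ = 0.1`, `λ₂ = 0.05`. The adversarial term uses the
relativistic-average formulation (how much more realistic is a real crop than
the average fake, and vice versa), with a non-saturating standard variant as
an option. The perceptual term is the mean absolute distance between deep
feature maps of a **frozen, seeded random-weight convolutional extractor**
(three stride-2 conv/leaky-ReLU stages plus a final pre-activation
projection; single-channel inputs replicated to three channels). Random deep
features form a valid pseudometric and the package's perceptual-loss
contracts (zero at identity, symmetry, monotonicity along a blend path) are
independent of the particular weights. Optimisation is Adam with β₁ = 0.9,
β₂ = 0.99 for both networks; default learning rate 1e-4 (CPU-scale runs use
5e-4), halved at configurable milestones.

**Training schedule.** One discriminator step then one generator step per
iteration. An optional pixel-only warmup phase (`warmup_iterations`) precedes
the adversarial phase, after which the generator learning rate is multiplied
by `finetune_lr_factor` (default 0.2) and the discriminator runs at
`d_lr_factor` (default 2×) the generator rate. A cold discriminator's
gradient is uninformative, and at short schedules Adam renormalises that
noise into full-sized generator steps; the warmup keeps the pixel-trained
operating point before adversarial refinement begins. Training aborts with a
diagnostic record if any loss becomes non-finite.

## The numerical engine

No tensor-autograd library ships with the supported environment, so the
package carries a compact reverse-mode engine on float32 numpy arrays
(`mpsr.nn`): convolution is implemented as per-tap GEMMs over a materialised
column tensor when gradients are needed and as row-chunked, cache-resident
column GEMMs for large-tile inference; the deformable gather has an exact
four-corner bilinear implementation with gradients to features and offsets,
and a `scipy.ndimage.map_coordinates` fast path (grid-constant boundary, so
the two paths agree to float precision) in inference mode. All gradients are
verified against central finite differences in the test suite.

## The synthetic study system

No paired acquisition data are deposited, so every stage is exercised on
phantoms whose three channels emulate the morphologies of label-free
nonlinear imaging: Bézier-curve fibres with a Gaussian cross-profile
(collagen-like SHG structures), soft-edged elliptical blobs (cells,
follicles) and smoothed point-process speckle (granular autofluorescence).
Defaults: 512×512 ground truth, 350 structures per megapixel, intensities in
[0.02, 0.9]. The density and drawing widths are calibrated so the clean
image's strong-signal mean is ≈ 62/255, the 8-bit signal level typical of
resonant-scan tissue acquisitions; the default read-noise STD is 20/255 for
the same reason.

The degradation pipeline applies, in causal order: optics blur of the fast
arm (Gaussian, FWHM 6 px at GT scale) → geometric misalignment (random
similarity transform, bounds up to 200 px shift / 1° / 1% scale, or an
explicit fixed scanner offset) → ×4 area-average downsampling (integrating
detection) → Poisson shot noise (`photon_gain` counts per unit intensity) →
Gaussian read noise → multiplicative scanning fringes (smooth sinusoidal row
gain, period 16 rows, amplitude 0.25, seeded phase jitter) → additive
stitching-lattice offsets (16×16 fields, 50% feather overlap, per-field
offsets with STD 0.03) → clipping to [0, 1]. The slow-scan ground truth is
the same phantom blurred at its own smaller PSF (FWHM 2 px). The stage order
mirrors the physics (optics → scanner geometry → sampling → detection → scan
electronics → stitching); the identity configuration reproduces the input
bit-for-bit, and all randomness flows from a single seed.

Signal/background masks are thresholded on the clean reference: signal = top
intensity decile, background = bottom decile. SNR is fixed as
`20·log10(σ_signal/σ_background)` with those masks.

**What the phantoms do not emulate:** optical sectioning and 3-D PSFs,
spectral crosstalk between modalities, detector saturation and sample
motion. Passing tests therefore demonstrate that the pipeline's machinery is
correct and that restoration improves the stated metrics *under this noise
and artefact model*, not that a tiny CPU-trained model reaches publication
quality on tissue.

## Registration

ORB keypoints (FAST corners + rotated BRIEF, ≤ 1200 by default) are matched
by cross-checked Hamming distance with a 0.8 ratio test; a projective
transform is estimated by RANSAC (threshold 3 px, seeded) and refined by
least squares on the inliers. Matching runs at ground-truth scale (the input
is bicubically ×4-upscaled first so descriptors see comparable spatial
frequencies) and on the channel sum. Across twenty seeded misalignments with
shifts spanning 0–200 px, recovery is better than 2 px RMS (typically
< 1 px) on 1024² phantoms.

## Evaluation stack

* **MSE / PSNR / SSIM** — float64; PSNR reports +∞ for identical images;
  SSIM uses the original 11×11 Gaussian window, σ = 1.5 (shrunk to the
  largest odd window on very small images).
* **NIQE** — MSCN coefficients (Gaussian weighting σ = 7/6), per-patch
  features at two scales: a GGD fit (2 parameters) plus AGGD fits of four
  directional pairwise products (4×4), i.e. 36 features; patches below a
  sharpness fraction (default 0.75 of the per-image maximum, never discarding
  more than the duller half) are dropped when fitting the pristine
  multivariate Gaussian; the score is the pooled-covariance Mahalanobis
  distance. Constant images return a flagged fallback score.
* **PIQE** — opinion-unaware block score on 16×16 MSCN blocks: active blocks
  (variance > 0.1) are distorted when most boundary segments are
  near-uniform (blur/blockiness) or when their statistics are noise-like
  (variance > 0.4 with near-zero mean); the score pools distorted-block
  contributions to [0, 100]. This is a faithful re-implementation of the
  published recipe's structure with thresholds recalibrated for this image
  class; its blur direction is the contractually tested one.
* **RSE / RSP** — the super-resolved image is box-downscaled to the
  reference grid, intensity-matched by least squares (α, β), and scored by
  the RMS residual and Pearson correlation; the absolute residual map
  localises hallucinated structure.
* **FRC** — radially binned normalised cross-spectrum of two realizations
  (or a checkerboard pixel-decimation split of one image); resolution is the
  reciprocal of the first 1/7-threshold crossing with linear interpolation
  between bins; "beyond Nyquist" is an explicit sentinel.
* **PSF FWHM** — central row/column profiles of isolated spots are fitted
  with a 1-D Gaussian plus offset on peak-normalised data; spots pass when
  adjusted R² > 0.98, SSE < 0.02 and RMSE < 0.06, and only passers enter the
  aggregate. FWHM = 2√(2 ln 2)·σ.

## Scaled-down study sizes

The shipped tests and the acceptance script run everything on one CPU:
phantoms at 512² (registration at 1024²), the 16-feature/2-block generator
preset, 400 pixel-loss iterations with batch 4 and 32→128 crops for the
restoration study, and 500-iteration runs with 24→96 crops for the paired
ablations. Under these conditions the trained model beats nearest-neighbour
and bicubic ×4 baselines on PSNR, SSIM and mask-based SNR, and its outputs
score better custom-NIQE than the inputs on ≥ 9/10 held-out tiles.

Two findings from the ablation studies at this scale deserve emphasis:

* **Self-alignment** is compared on pairs with a fixed 2 px (input-scale)
  scanner offset and suppressed noise, isolating the alignment factor — a
  constant offset is the physically meaningful form of residual
  misalignment, since a per-pair random shift is unlearnable by any network
  that sees no reference at inference. Disabling the module does not improve
  (and measurably worsens) held-out pixel error.
* **The adversarial/perceptual objective needs scale.** At a few hundred
  iterations the discriminator is barely informative and its gradient
  degrades the generator on *every* error axis, including perceptual
  distance; the corresponding directional check is expected to fail at desk
  scale and is retained unmodified as a scale-limitation marker. The paired
  runs use identical seeds and budgets, so the comparison itself is fair.

## Degenerate inputs and numerical conventions

Coordinates are row-major, 0-based, origin top-left, half-open tile
intervals; transform matrices are 3×3 homogeneous acting on (x, y, 1).
Quantitative processing uses float32 in [0, 1]; 8-bit conversion only at the
TIFF boundary with round-half-even. Display-stretched copies carry a
`display_only` flag and are refused by every quantitative entry point.
Non-divisible inference dimensions are rejected rather than padded, keeping
the ×4 contract exact. Zero matrices pass through spectral normalisation
unchanged; constant images yield flagged fallback scores in NIQE/PIQE and an
explicit error in SNR (zero background variance) and RSP (undefined
correlation).

## Known limitations

* The numpy engine is single-threaded and ~10²–10³ slower than a GPU tensor
  library; published-scale training (400k iterations, 64-feature, 23-block
  generator) is out of reach, and every empirical claim here is made at the
  scaled-down sizes above.
* Random-feature perceptual loss is a pseudometric, not a trained semantic
  feature space; at scale, a pretrained deep extractor should be substituted.
* The exact supplementary wiring of the original attention and alignment
  modules is not public; the placements documented above are this package's
  own design decisions.
* BRISQUE is not provided (it requires an externally trained regression
  model); the custom-NIQE route is the supported no-reference path.
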