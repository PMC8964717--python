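# mpsr — restoration of fast-scan multiphoton microscopy images

Laser-scanning nonlinear microscopes trade speed against quality: a
galvo-resonant scanner covers a large field in seconds but produces noisy,
fringed, undersampled images, while a dual-axis galvo scan of the same field
takes ten times longer and yields the clean, high-resolution reference.
`mpsr` is a toolkit for closing that gap computationally. It restores fast
resonant-scan images — three modality channels: two-photon FAD
autofluorescence, second-harmonic generation from collagen, and three-photon
NADH autofluorescence — into denoised, ×4 super-resolved images matching the
slow-scan domain, and ships everything needed to develop and evaluate such a
restorer without access to a microscope:

* **`mpsr.synth`** — paired-acquisition simulator: multimodal phantoms
  (fibres / cell-like blobs / granular texture) degraded by optics blur,
  scanner misalignment, ×4 area-average undersampling, Poisson shot noise,
  Gaussian read noise, multiplicative scanning fringes and stitching-lattice
  seams, all driven by one seed.
* **`mpsr.registration`** — ORB (oriented FAST + rotated BRIEF) feature
  matching with RANSAC to warp the fast-scan image onto the slow-scan frame.
* **`mpsr.generator`** — the restoration network: self-alignment via a
  pyramid of cascaded deformable convolutions (offsets predicted from the
  input features), a trunk of residual-in-residual dense blocks with channel
  (squeeze-and-excitation) and spatial attention, a global skip, and two
  nearest-neighbour ×2 upsampling stages,

      ŷ = G(x),   G = up₄ ∘ (id + trunk) ∘ align ∘ conv,
      trunk = RRDAB₁ ∘ … ∘ RRDAB_N,  RRDAB(x) = x + β·SA(CA(D₃D₂D₁(x)))

* **`mpsr.adversary`** — spectrally normalised discriminator, perceptual
  loss on frozen deep features, and the composite objective
  `L = L₁ + λ₁·L_percep + λ₂·L_adv` with λ₁ = 0.1, λ₂ = 0.05
  (relativistic-average adversarial term).
* **`mpsr.pipeline`** — tiling/cropping/augmentation, the alternating GAN
  training loop (Adam, β₁ = 0.9, β₂ = 0.99), and tiled 4×4 inference for
  large images with a stitching-seam metric.
* **`mpsr.metrics`** — MSE/PSNR/SSIM, mask-based SNR, a custom-trainable
  NIQE and a block-based PIQE, resolution-scaled error/Pearson (RSE/RSP)
  with error maps, Fourier-ring-correlation resolution, and Gaussian PSF
  FWHM fitting with fit-quality gates (adj. R² > 0.98, SSE < 0.02,
  RMSE < 0.06).

The network and its training machinery run on a compact reverse-mode
autodiff engine over numpy arrays (`mpsr.nn`) — no GPU or deep-learning
framework is required; everything in the test suite runs on one CPU.

## Worked example

Simulate paired acquisitions, train a small restorer, and evaluate it:

```python
import numpy as np
from mpsr.synth import PhantomSpec, DegradationConfig, generate_phantom, degrade
from mpsr.generator import tiny_config, build_generator
from mpsr.pipeline import (TrainConfig, prepare_training_tiles, train,
                           predict_large, bicubic_x4)
from mpsr.adversary import LossWeights
from mpsr.metrics import psnr, ssim, snr_db

def acquire(seed):
    gt = generate_phantom(PhantomSpec(shape_gt=(512, 512), seed=seed))
    cfg = DegradationConfig(seed=100 + seed, misalign_max_shift_px=0,
                            misalign_max_rot_deg=0, misalign_max_scale=0)
    return degrade(gt, cfg)          # preregistered pair

pairs, test = [acquire(s) for s in (1, 2, 3)], acquire(9)
tiles = [t for p in pairs for c in range(3)
         for t in prepare_training_tiles(p.input_image[:, :, c],
                                         p.gt_image[:, :, c],
                                         tile=64, stride=32, trim=16)]

gen = build_generator(tiny_config())          # 16 feats, 2 blocks: CPU scale
cfg = TrainConfig(batch_size=4, input_crop=32, gt_crop=128, iterations=400,
                  learning_rate=5e-4, lr_milestones=(250,), seed=0,
                  loss_weights=LossWeights(1.0, 0.0, 0.0))
gen, history = train(tiles, gen, None, cfg)

restored = predict_large(test.input_image, gen)   # (512, 512, 3), x4 of input
for name, img in [("bicubic", bicubic_x4(test.input_image)),
                  ("restored", restored)]:
    p = np.mean([psnr(img[:, :, c], test.gt_image[:, :, c]) for c in range(3)])
    s = np.mean([ssim(img[:, :, c], test.gt_image[:, :, c]) for c in range(3)])
    snr = snr_db(img, test.signal_mask, test.background_mask)
    print(f"{name:9s} PSNR {p:5.2f} dB   SSIM {s:.3f}   SNR {snr:6.2f} dB")
```

Output (seeds as above, ~4 minutes on one CPU):

```
bicubic   PSNR 21.83 dB   SSIM 0.384   SNR   8.01 dB
restored  PSNR 22.54 dB   SSIM 0.684   SNR  23.27 dB
```

The restored image beats bicubic ×4 upsampling on fidelity (PSNR, and
structural similarity more than 1.7×) and raises the mask-based
signal-to-noise ratio by ~15 dB by flattening the read noise, fringes and
stitching seams that dominate the fast-scan background.

The same stages are available as a CLI (`mpsr simulate / register / train /
predict / evaluate / fit-niqe`); each subcommand validates its YAML config,
seeds all randomness from one `--seed`, and writes a run manifest next to
its outputs.

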