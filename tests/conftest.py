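"""Shared fixtures: phantoms, paired acquisitions and scaled-down datasets.

Everything is generated programmatically and seeded; session scope keeps the
expensive objects (phantoms, degraded pairs) shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from mpsr.pipeline import prepare_training_tiles
from mpsr.registration import PlanarTransform
from mpsr.synth import (DegradationConfig, PhantomSpec, degrade,
                        generate_phantom, identity_config)

TRAIN_SEEDS = (1, 2, 3)
TEST_SEED = 9


@pytest.fixture(scope="session")
def phantom_factory():
    cache = {}

    def make(seed, shape=(512, 512), **kwargs):
        key = (seed, shape, tuple(sorted(kwargs.items())))
        if key not in cache:
            cache[key] = generate_phantom(
                PhantomSpec(shape_gt=shape, seed=seed, **kwargs))
        return cache[key]

    return make


@pytest.fixture(scope="session")
def aligned_pairs(phantom_factory):
    """Preregistered (zero-misalignment) train/test acquisitions at default
    degradation: the criterion-5 study conditions."""
    def make(seed):
        cfg = DegradationConfig(seed=100 + seed, misalign_max_shift_px=0.0,
                                misalign_max_rot_deg=0.0, misalign_max_scale=0.0)
        return degrade(phantom_factory(seed), cfg)

    return {"train": [make(s) for s in TRAIN_SEEDS], "test": make(TEST_SEED)}


# fixed scanner offset: 2 px residual shift at input scale (8 px at GT scale)
RESIDUAL_SHIFT = PlanarTransform.from_similarity(shift_xy=(8.0, -8.0))


@pytest.fixture(scope="session")
def misaligned_pairs(phantom_factory):
    """Low-noise pairs with a fixed 2 px (input-scale) residual misalignment:
    the ablation study conditions (noise suppressed to isolate alignment)."""
    base = identity_config(downsample_factor=4, psf_fwhm_input_px=6.0,
                           psf_fwhm_gt_px=2.0, read_noise_std=0.01)

    def make(seed):
        from dataclasses import replace
        return degrade(phantom_factory(seed), replace(base, seed=100 + seed),
                       misalign=RESIDUAL_SHIFT)

    return {"train": [make(s) for s in TRAIN_SEEDS], "test": make(TEST_SEED)}


def tiles_from_pairs(pairs, tile=64, stride=32, trim=16):
    tiles = []
    for p in pairs:
        for c in range(p.input_image.shape[2]):
            tiles += prepare_training_tiles(p.input_image[:, :, c],
                                            p.gt_image[:, :, c],
                                            tile=tile, stride=stride, trim=trim)
    return tiles


def upsample_nearest(img: np.ndarray, f: int = 4) -> np.ndarray:
    return np.repeat(np.repeat(img, f, axis=0), f, axis=1)
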