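"""TIFF I/O and image records.

Images travel as :class:`ImageRecord`: an (H, W, C) raster with bit depth,
channel names, pixel size and provenance metadata.  The quantitative
pipeline works on float32 in [0, 1]; 8-bit conversion happens only at the
I/O boundary (round-half-even).  Metadata rides in the TIFF description tag
as JSON, so a write/read round trip is bit-exact for both supported depths
(uint8 and float32).

Display-stretched copies are flagged ``display_only`` and are refused by
every quantitative entry point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

DEFAULT_CHANNEL_NAMES = ("FAD_2PA", "SHG", "NADH_3PA")  # mapped to R, G, B


class DisplayOnlyError(ValueError):
    """A display-stretched image was passed to a quantitative path."""


@dataclass
class ImageRecord:
    pixels: np.ndarray                      # (H, W, C) uint8 or float32
    bit_depth: str = "float32"              # "uint8" | "float32"
    channel_names: tuple = DEFAULT_CHANNEL_NAMES
    pixel_size_um: float | None = None
    display_only: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3 or px.shape[2] > 3:
            raise ValueError("pixels must be (H, W, C<=3)")
        if self.bit_depth == "uint8":
            px = px.astype(np.uint8)
        elif self.bit_depth == "float32":
            px = px.astype(np.float32)
        else:
            raise ValueError(f"unsupported bit depth {self.bit_depth!r}")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.pixels = px
        self.channel_names = tuple(self.channel_names)[:px.shape[2]]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    def as_float(self) -> np.ndarray:
        """Pixels as float32 in [0, 1] (quantitative-path guard applies)."""
        ensure_quantitative(self)
        if self.bit_depth == "uint8":
            return self.pixels.astype(np.float32) / 255.0
        return self.pixels.astype(np.float32)

    @classmethod
    def from_float(cls, arr: np.ndarray, bit_depth: str = "float32", **kwargs):
        arr = np.asarray(arr, dtype=np.float32)
        if bit_depth == "uint8":
            # round-half-even at the 8-bit boundary
            arr = np.rint(np.clip(arr, 0, 1) * 255.0).astype(np.uint8)
        return cls(pixels=arr, bit_depth=bit_depth, **kwargs)


def ensure_quantitative(record: ImageRecord):
    if record.display_only:
        raise DisplayOnlyError(
            "display-only image: percentile-stretched copies are for "
            "visualisation and cannot enter quantitative processing")


def write_tiff(record: ImageRecord, path) -> str:
    meta = {
        "bit_depth": record.bit_depth,
        "channel_names": list(record.channel_names),
        "pixel_size_um": record.pixel_size_um,
        "display_only": record.display_only,
        "provenance": record.provenance,
    }
    px = record.pixels
    if px.shape[2] == 1:
        px = px[:, :, 0]
    tifffile.imwrite(str(path), px, description=json.dumps(meta))
    return str(path)


def read_tiff(path) -> ImageRecord:
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        arr = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError):
                meta = {}
    if arr.dtype == np.uint8:
        depth = "uint8"
    elif arr.dtype == np.float32:
        depth = "float32"
    else:
        raise ValueError(
            f"unsupported TIFF sample type {arr.dtype}: only 8-bit unsigned "
            "and 32-bit float are supported")
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return ImageRecord(
        pixels=arr, bit_depth=depth,
        channel_names=tuple(meta.get("channel_names", DEFAULT_CHANNEL_NAMES)),
        pixel_size_um=meta.get("pixel_size_um"),
        display_only=bool(meta.get("display_only", False)),
        provenance=meta.get("provenance", {}))


def adjust_display_range(record: ImageRecord, low_pct: float = 1.0,
                         high_pct: float = 99.0) -> ImageRecord:
    """Percentile contrast stretch for visualisation only.

    The returned record is flagged ``display_only`` and will be rejected by
    quantitative entry points.
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("require 0 <= low_pct < high_pct <= 100")
    arr = record.pixels.astype(np.float32)
    if record.bit_depth == "uint8":
        arr = arr / 255.0
    lo = np.percentile(arr, low_pct)
    hi = np.percentile(arr, high_pct)
    if hi <= lo:
        import warnings
        warnings.warn("constant image: display range not adjusted")
        out = arr
    elif (low_pct, high_pct) == (0.0, 100.0):
        out = arr
    else:
        out = np.clip((arr - lo) / (hi - lo), 0.0, 1.0)
    return ImageRecord.from_float(out, bit_depth=record.bit_depth,
                                  channel_names=record.channel_names,
                                  pixel_size_um=record.pixel_size_um,
                                  display_only=True,
                                  provenance={**record.provenance,
                                              "display_stretch": [low_pct, high_pct]})
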