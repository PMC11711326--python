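"""Image batches, manifests, and disk I/O.

Images live in two ranges: stored files are 8- or 16-bit integers, the model
consumes floats in [-1, 1] (a linear map of the stored range). Manifests are
CSV tables with columns ``path, condition_id, modality, batch_id, split``.
Multi-channel images are written channels-first as TIFF; single- or
three-channel images may also be PNG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

MANIFEST_COLUMNS = ["path", "condition_id", "modality", "batch_id", "split"]


@dataclass
class ImageBatch:
    """Float image tensor (B, C, H, W) in the model range [-1, 1]."""

    pixels: np.ndarray
    channel_names: list = field(default_factory=list)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be (batch, channels, height, width)")
        b, c, h, w = self.pixels.shape
        if c < 1:
            raise ValueError("need at least one channel")
        if h % 8 or w % 8:
            raise ValueError("height and width must be divisible by 8")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixels contain non-finite values")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(c)]

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class ArrayDataset:
    """In-memory dataset: images in model range plus per-image labels."""

    images: np.ndarray
    condition_ids: np.ndarray
    batch_ids: np.ndarray | None = None
    manifest: pd.DataFrame | None = None

    def __len__(self):
        return len(self.images)


def to_model_range(stored, bit_depth=8):
    """Linear map of integer-stored pixels onto [-1, 1]."""
    top = float(2**bit_depth - 1)
    return np.asarray(stored, dtype=np.float64) / top * 2.0 - 1.0


def to_stored_range(model_pixels, bit_depth=8):
    """Inverse map, clipped and quantized."""
    top = 2**bit_depth - 1
    scaled = (np.clip(model_pixels, -1.0, 1.0) + 1.0) / 2.0 * top
    dtype = np.uint8 if bit_depth <= 8 else np.uint16
    return np.round(scaled).astype(dtype)


def write_image(path, pixels_model, bit_depth=8):
    """Write a single (C, H, W) model-range image as TIFF or PNG."""
    path = Path(path)
    stored = to_stored_range(pixels_model, bit_depth)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, stored)
    else:
        arr = stored[0] if stored.shape[0] == 1 else np.moveaxis(stored, 0, -1)
        iio.imwrite(path, arr)
    return path


def read_image(path, bit_depth=8):
    """Read a stored image back into model range, channels-first."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
        if arr.ndim == 3:
            arr = np.moveaxis(arr, -1, 0)
    if arr.ndim == 2:
        arr = arr[None]
    return to_model_range(arr, bit_depth)


def write_manifest(df, path):
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    df.to_csv(path, index=False)


def read_manifest(path):
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    return df


def load_dataset(manifest_path, root=None, bit_depth=8):
    """Materialize a manifest into an :class:`ArrayDataset`."""
    df = read_manifest(manifest_path)
    root = Path(root) if root else Path(manifest_path).parent
    images = np.stack([read_image(root / p, bit_depth) for p in df["path"]])
    return ArrayDataset(
        images=images,
        condition_ids=df["condition_id"].to_numpy(),
        batch_ids=df["batch_id"].to_numpy(),
        manifest=df,
    )
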