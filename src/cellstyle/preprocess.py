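"""Plate-level preprocessing: illumination correction, cropping, QC, patching.

The illumination pipeline follows the retrospective flatfield approach used
for high-content plates: a per-plate, per-channel flatfield is the smoothed
pixelwise 10th percentile across the plate's images; each image is divided
by it, clipped below at 1, log-transformed, clipped above at 5, then
rescaled per image to [0, 255] and quantized to 8 bits.

Coordinates are 0-based with x = column and y = row; crops take the
half-open window [c - side/2, c + side/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.transform import resize

log = logging.getLogger(__name__)


@dataclass
class PlateStack:
    """Images of one plate: array (n_images, C, H, W), any intensity scale."""

    plate_id: str
    images: np.ndarray
    bit_depth: int = 16

    def __post_init__(self):
        self.images = np.asarray(self.images)
        if self.images.ndim != 4:
            raise ValueError("plate images must be (n, C, H, W)")


@dataclass
class CellCrop:
    pixels: np.ndarray            # (C, side, side), 8-bit intensity domain
    source_id: str
    centre: tuple                 # (x, y), 0-based
    variance: float = field(default=np.nan)
    blur: float = field(default=np.nan)


def illumination_correct(plate: PlateStack, flatfield_sigma=50.0, log_clip=5.0,
                         rescale="image"):
    """Return an 8-bit illumination-corrected copy of the plate.

    ``rescale`` selects whether the final linear stretch to [0, 255] uses
    per-image extremes (default) or plate-wide extremes.
    """
    imgs = plate.images.astype(np.float64, copy=False)
    n, c, h, w = imgs.shape
    if n == 1:
        log.warning("plate %s has a single image; flatfield is that image itself",
                    plate.plate_id)
    corrected = np.empty_like(imgs)
    for ch in range(c):
        flat = np.percentile(imgs[:, ch], 10, axis=0)
        flat = ndimage.gaussian_filter(flat, flatfield_sigma)
        if (flat <= 0).any():
            positive = flat[flat > 0]
            if positive.size == 0:
                raise ValueError(f"flatfield for plate {plate.plate_id} is all zero")
            log.warning("flatfield zeros on plate %s channel %d replaced",
                        plate.plate_id, ch)
            flat = np.where(flat <= 0, positive.min(), flat)
        ratio = imgs[:, ch] / flat
        ratio = np.clip(ratio, 1.0, None)
        transformed = np.clip(np.log(ratio), None, log_clip)
        corrected[:, ch] = transformed
    out = np.empty_like(corrected, dtype=np.uint8)
    if rescale == "plate":
        out = _stretch_to_8bit(corrected)
    else:
        for i in range(n):
            for ch in range(c):
                out[i, ch] = _stretch_to_8bit(corrected[i, ch])
    return PlateStack(plate_id=plate.plate_id, images=out, bit_depth=8)


def _stretch_to_8bit(img, degenerate_span=1e-9):
    """Linear min-max stretch to [0, 255]; a (numerically) constant input
    maps to zero rather than amplifying float noise."""
    lo, hi = img.min(), img.max()
    if hi - lo <= degenerate_span:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.round((img - lo) / (hi - lo) * 255).astype(np.uint8)


def crop_single_cells(image, centres, side=96, border=48, source_id="image"):
    """Crop side x side windows around centres, dropping border-adjacent ones.

    ``centres`` is a sequence of (x, y); a centre closer than ``border`` to
    any edge is dropped. Returns (crops, n_dropped).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[None]
    _, h, w = image.shape
    half = side // 2
    if border < half:
        raise ValueError("border must be at least side/2 so crops fit")
    crops, dropped = [], 0
    for x, y in centres:
        if x < border or x > w - border or y < border or y > h - border:
            dropped += 1
            continue
        x0, y0 = int(round(x)) - half, int(round(y)) - half
        crops.append(
            CellCrop(
                pixels=image[:, y0 : y0 + side, x0 : x0 + side].copy(),
                source_id=source_id,
                centre=(x, y),
            )
        )
    return crops, dropped


def perceptual_blur(image):
    """Normalized perceptual blur in [0, 1] (1 = maximal blur).

    Re-blur comparison: the image is blurred with a 9-tap box filter along
    each axis; the blur estimate is how little the neighbouring-pixel
    variation decreases under re-blurring (an already-blurred image loses
    almost nothing). The per-axis scores are combined with max.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=0)
    kernel = np.ones(9) / 9.0
    b_ver = ndimage.convolve1d(img, kernel, axis=0, mode="nearest")
    b_hor = ndimage.convolve1d(img, kernel, axis=1, mode="nearest")
    d_f_ver = np.abs(np.diff(img, axis=0))
    d_f_hor = np.abs(np.diff(img, axis=1))
    d_b_ver = np.abs(np.diff(b_ver, axis=0))
    d_b_hor = np.abs(np.diff(b_hor, axis=1))
    v_ver = np.maximum(0.0, d_f_ver - d_b_ver)
    v_hor = np.maximum(0.0, d_f_hor - d_b_hor)
    s_f_ver, s_f_hor = d_f_ver.sum(), d_f_hor.sum()
    if s_f_ver == 0 and s_f_hor == 0:
        return 1.0  # constant image: maximally blur-like
    b1 = (s_f_ver - v_ver.sum()) / s_f_ver if s_f_ver > 0 else 1.0
    b2 = (s_f_hor - v_hor.sum()) / s_f_hor if s_f_hor > 0 else 1.0
    return float(max(b1, b2))


def qc_filter(crops, variance_min=2000.0, blur_max=0.65):
    """Keep crops with pixel variance >= variance_min and blur <= blur_max.

    Variance is computed over all channels flattened, in the 8-bit domain.
    Returns (retained crops, report DataFrame with one row per input crop).
    """
    retained, rows = [], []
    for i, crop in enumerate(crops):
        var = float(np.var(crop.pixels))
        blur = perceptual_blur(crop.pixels)
        crop.variance, crop.blur = var, blur
        if var < variance_min:
            reason = "variance"
        elif blur > blur_max:
            reason = "blur"
        else:
            reason = ""
            retained.append(crop)
        rows.append(
            {
                "crop": i,
                "source_id": crop.source_id,
                "variance": var,
                "blur": blur,
                "retained": reason == "",
                "reason": reason,
            }
        )
    return retained, pd.DataFrame(rows)


def patch_large_fov(image, patch=256, resize_to=128):
    """Tile an image into non-overlapping patches and downsample each.

    Partial edge tiles are discarded. Returns a list of (C, resize_to,
    resize_to) arrays in the input intensity scale.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[None]
    c, h, w = image.shape
    if h < patch or w < patch:
        raise ValueError("image smaller than the patch size")
    patches = []
    for i in range(h // patch):
        for j in range(w // patch):
            tile = image[:, i * patch : (i + 1) * patch, j * patch : (j + 1) * patch]
            small = np.stack(
                [resize(tile[ch], (resize_to, resize_to), anti_aliasing=True,
                        preserve_range=True) for ch in range(c)]
            )
            patches.append(small)
    return patches


def segment_nuclei_patches(image, patch=96, nuclear_channel=0, min_area=40,
                           source_id="image"):
    """Otsu-segment the nuclear channel and crop one patch per object.

    Connected components above ``min_area`` become seeds; a patch is cut
    around each seed centroid with the same border rule as
    :func:`crop_single_cells`. Merged nuclei yield a single patch.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[None]
    nuclear = image[nuclear_channel]
    if nuclear.max() == nuclear.min():
        log.info("no foreground found in %s", source_id)
        return []
    mask = nuclear > threshold_otsu(nuclear)
    if not mask.any():
        log.info("no foreground found in %s", source_id)
        return []
    labelled = label(mask)
    centres = [
        (prop.centroid[1], prop.centroid[0])
        for prop in regionprops(labelled)
        if prop.area >= min_area
    ]
    crops, _ = crop_single_cells(
        image, centres, side=patch, border=patch // 2, source_id=source_id
    )
    return crops
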