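"""Synthetic high-content image generator.

Renders labeled multi-channel cell images whose appearance depends on a
condition (phenotype) parameter set and a batch-effect parameter set, so the
model, preprocessing and metric modules can be exercised offline against
known ground truth. A phenotype controls nuclear size and shape, cell
density, per-channel intensity gain and cytoplasm texture frequency --
caricatures of the effects perturbations have on stained cells (intensity
loss, nuclear shrinkage, cell depletion). A batch effect applies per-channel
multiplicative gain, additive offset and optical blur, mimicking technical
variation between acquisition sources.

Not modeled: stain physics, optics beyond Gaussian blur, cell-cycle
heterogeneity, or realistic textures. Tests passing on these images show the
machinery is correct, not that real screens will behave identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .data import ArrayDataset, write_image, write_manifest
from .utils import stream_rng


@dataclass
class PhenotypeSpec:
    condition_id: int
    nuclear_radius: float = 4.0          # px
    cell_rate: float = 6.0               # expected cells per image (Poisson)
    intensity_gain: tuple = (1.0, 1.0, 1.0)   # per channel
    texture_frequency: float = 2.0       # cytoplasm texture cycles per cell
    eccentricity: float = 1.3            # nuclear axis ratio
    is_control: bool = False

    def __post_init__(self):
        if self.nuclear_radius <= 0 or self.cell_rate < 0:
            raise ValueError("phenotype parameters must be positive")
        if any(g < 0 for g in self.intensity_gain):
            raise ValueError("intensity gains must be non-negative")


@dataclass
class BatchEffectSpec:
    batch_id: int
    gain: tuple = (1.0, 1.0, 1.0)
    offset: tuple = (0.0, 0.0, 0.0)
    blur_sigma: float = 0.0

    def __post_init__(self):
        if any(g <= 0 for g in self.gain):
            raise ValueError("batch gains must be > 0")


IDENTITY_BATCH = BatchEffectSpec(batch_id=0)


def _per_channel(values, channels):
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim == 0:
        arr = np.full(channels, float(arr))
    if arr.size < channels:
        arr = np.concatenate([arr, np.full(channels - arr.size, arr[-1])])
    return arr[:channels]


def render_image(spec, batch, size=48, channels=3, rng=None):
    """Render one image; returns (image (C, size, size) in [0, 1], cell count).

    Cells are placed from a Poisson(cell_rate) draw with overlap-limited
    rejection sampling. The nuclear stain lives in channel 0; remaining
    channels carry a textured cytoplasm annulus. Batch gain/offset/blur are
    applied last.
    """
    if size % 8:
        raise ValueError("size must be divisible by 8")
    rng = rng or np.random.default_rng()
    img = np.clip(
        rng.normal(0.05, 0.015, size=(channels, size, size)), 0.0, None
    )
    n_cells = int(rng.poisson(spec.cell_rate))
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    centres = []
    min_dist = 2.2 * spec.nuclear_radius
    placed = 0
    for _ in range(n_cells):
        for _ in range(60):
            cx, cy = rng.uniform(2, size - 2, size=2)
            if all((cx - ox) ** 2 + (cy - oy) ** 2 > min_dist**2 for ox, oy in centres):
                centres.append((cx, cy))
                placed += 1
                break
    gains = _per_channel(spec.intensity_gain, channels)
    for cx, cy in centres:
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        a = spec.nuclear_radius * spec.eccentricity
        b = spec.nuclear_radius / spec.eccentricity
        r2 = (u / a) ** 2 + (v / b) ** 2
        nucleus = 0.85 * np.exp(-0.5 * r2 * 4.0)
        img[0] += gains[0] * nucleus
        if channels > 1:
            r = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
            ring_mid = 2.4 * spec.nuclear_radius
            ring = np.exp(-0.5 * ((r - ring_mid) / (0.8 * spec.nuclear_radius)) ** 2)
            phase = rng.uniform(0, 2 * np.pi)
            texture = 1.0 + 0.45 * np.sin(
                2 * np.pi * spec.texture_frequency * r / ring_mid + phase
            )
            for c in range(1, channels):
                img[c] += 0.55 * gains[c] * ring * texture / 1.45
    bgain = _per_channel(batch.gain, channels)
    boffset = _per_channel(batch.offset, channels)
    img = img * bgain[:, None, None] + boffset[:, None, None]
    if batch.blur_sigma > 0:
        for c in range(channels):
            img[c] = ndimage.gaussian_filter(img[c], batch.blur_sigma)
    return np.clip(img, 0.0, 1.0), placed


@dataclass
class SyntheticDataset:
    images: np.ndarray               # (N, C, H, W) in [0, 1]
    manifest: pd.DataFrame           # condition_id, batch_id, split per image
    counts: np.ndarray               # ground-truth cell count per image
    specs: dict                      # condition_id -> PhenotypeSpec
    batches: dict                    # batch_id -> BatchEffectSpec

    def training_set(self, label="condition", split=None):
        """Model-range view (pixels in [-1, 1]) labeled by condition or batch."""
        mask = (
            np.ones(len(self.images), dtype=bool)
            if split is None
            else (self.manifest["split"] == split).to_numpy()
        )
        labels = (
            self.manifest["condition_id"] if label == "condition" else self.manifest["batch_id"]
        ).to_numpy()[mask]
        return ArrayDataset(
            images=self.images[mask] * 2.0 - 1.0,
            condition_ids=labels,
            batch_ids=self.manifest["batch_id"].to_numpy()[mask],
            manifest=self.manifest[mask].reset_index(drop=True),
        )


def make_dataset(
    specs,
    batches,
    n_per_cell_of_design,
    size=48,
    channels=3,
    seed=0,
    test_fraction=0.25,
):
    """Full crossing of conditions x batches with n images per design cell."""
    if not specs or not batches:
        raise ValueError("need at least one phenotype spec and one batch spec")
    rows, images, counts = [], [], []
    for spec in specs:
        for batch in batches:
            rng = stream_rng(
                seed, "render", f"cond{spec.condition_id}", f"batch{batch.batch_id}"
            )
            for i in range(n_per_cell_of_design):
                img, count = render_image(spec, batch, size, channels, rng)
                images.append(img)
                counts.append(count)
                rows.append(
                    {
                        "path": (
                            f"img_c{spec.condition_id}_b{batch.batch_id}_{i:04d}.tiff"
                        ),
                        "condition_id": spec.condition_id,
                        "modality": "drug",
                        "batch_id": batch.batch_id,
                        "split": "test" if (i % max(1, round(1 / test_fraction))) == 0
                        else "train",
                    }
                )
    manifest = pd.DataFrame(rows)
    return SyntheticDataset(
        images=np.stack(images),
        manifest=manifest,
        counts=np.asarray(counts),
        specs={s.condition_id: s for s in specs},
        batches={b.batch_id: b for b in batches},
    )


def save_dataset(dataset: SyntheticDataset, out_dir, bit_depth=8):
    """Write images + manifest + ground truth to disk; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path, img in zip(dataset.manifest["path"], dataset.images):
        write_image(out / path, img * 2.0 - 1.0, bit_depth)
    manifest_path = out / "manifest.csv"
    write_manifest(dataset.manifest, manifest_path)
    pd.DataFrame(
        {"path": dataset.manifest["path"], "cell_count": dataset.counts}
    ).to_json(out / "ground_truth.json", orient="records")
    return manifest_path


def make_embedding_table(specs, dim=8, structure="line", seed=0, span=3.0):
    """Condition embeddings whose geometry mirrors phenotype geometry.

    line: embeddings sit on a straight line, position proportional to the
    mean intensity gain of the condition (so embedding distance is exactly
    monotone in gain difference), linearly rescaled so the largest pairwise
    distance equals ``span``. The span is expressed in units of the unit-
    variance noise prior the condition encoder concatenates with the
    embedding: real chemical descriptors of distinct compounds are far apart
    on that scale, so the default keeps conditions well separated relative
    to style noise. clusters: one tight group per distinct phenotype family
    (conditions sharing a spec template).
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = stream_rng(seed, "embedding_table")
    if structure == "line":
        direction = rng.standard_normal(dim)
        direction /= np.linalg.norm(direction)
        origin = rng.standard_normal(dim) * 0.1
        strengths = {
            spec.condition_id: float(np.mean(spec.intensity_gain)) for spec in specs
        }
        gap = max(strengths.values()) - min(strengths.values())
        scale = span / gap if gap > 0 else 1.0
        return {
            cid: origin + scale * strength * direction
            for cid, strength in strengths.items()
        }
    if structure == "clusters":
        families = {}
        table = {}
        for spec in specs:
            key = (
                round(spec.nuclear_radius, 3),
                round(spec.texture_frequency, 3),
                round(float(np.mean(spec.intensity_gain)), 3),
            )
            if key not in families:
                families[key] = rng.standard_normal(dim) * 3.0
            table[spec.condition_id] = families[key] + rng.standard_normal(dim) * 0.05
        return table
    raise ValueError(f"unknown structure {structure!r}")
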