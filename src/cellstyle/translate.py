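"""Inference: perturbation prediction, style interpolation, batch correction.

At test time a transformation runs the four inference steps: draw z from a
standard normal, map the target condition's embedding (plus z) to a style
with the condition encoder, encode the source image to its content map, and
decode the content under the new style. Unseen conditions enter as raw
embedding vectors of a registered modality; no label for the *source* image
is needed, so unseen sources work too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ag
from .ag import Tensor
from .data import ArrayDataset
from .models import StyleTransferModel
from .utils import stream_rng


@dataclass
class TransformRequest:
    images: np.ndarray                      # (B, C, H, W) in [-1, 1]
    target_condition: int | None = None     # registered condition id
    target_embedding: np.ndarray | None = None  # raw vector for unseen conditions
    target_modality: str = "drug"
    n_samples: int = 1
    seed: int = 0

    def __post_init__(self):
        if (self.target_condition is None) == (self.target_embedding is None):
            raise ValueError("specify exactly one of target_condition / target_embedding")


def transform(request: TransformRequest, model: StyleTransferModel):
    """Style-transfer the request's images to the target condition.

    Returns an array (n_samples, B, C, H, W); each sample uses an
    independent noise draw, so a trained model produces phenotype variants.
    """
    x = np.asarray(request.images, dtype=np.float64)
    rng = stream_rng(request.seed, "transform")
    if request.target_embedding is not None:
        emb = np.asarray(request.target_embedding, dtype=np.float64).ravel()
        mod = request.target_modality
        expected = model.cfg.modalities.get(mod)
        if expected is None:
            raise KeyError(f"modality {mod!r} not registered with the model")
        if emb.size != expected:
            raise ValueError(
                f"embedding length {emb.size} != registered dimension {expected}"
            )
    outs = []
    with ag.no_grad():
        content = model.encode_content(x)
        for _ in range(request.n_samples):
            z = model.sample_noise(rng, x.shape[0])
            if request.target_condition is not None:
                style = model.encode_condition(request.target_condition, z)
            else:
                style = model.encode_embedding(request.target_modality, emb, z)
            outs.append(model.decode(content, style).data)
    return np.stack(outs)


def interpolate_styles(
    image,
    embedding_a,
    embedding_b,
    n_steps,
    model: StyleTransferModel,
    modality="drug",
    seed=0,
    space="embedding",
):
    """Decode a source image along the line between two condition embeddings.

    A single shared noise draw is used for every step, so the sweep isolates
    the embedding's effect. ``space`` selects whether interpolation happens
    in embedding space (before the condition encoder; default, the route an
    unseen compound enters by) or directly in style space.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    ea = np.asarray(embedding_a, dtype=np.float64).ravel()
    eb = np.asarray(embedding_b, dtype=np.float64).ravel()
    if ea.size != eb.size:
        raise ValueError("embeddings must share a modality (and dimension)")
    x = np.asarray(image, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    rng = stream_rng(seed, "interpolate")
    z = model.sample_noise(rng, x.shape[0])
    alphas = np.linspace(0.0, 1.0, n_steps)
    frames = []
    with ag.no_grad():
        content = model.encode_content(x)
        if space == "style":
            sa = model.encode_embedding(modality, ea, z)
            sb = model.encode_embedding(modality, eb, z)
        for a in alphas:
            if space == "embedding":
                style = model.encode_embedding(modality, (1 - a) * ea + a * eb, z)
            else:
                style = Tensor((1 - a) * sa.data + a * sb.data)
            frames.append(model.decode(content, style).data)
    return np.stack(frames)


def batch_correct(dataset: ArrayDataset, reference_batch_id, model, seed=0):
    """Transport every image to the reference batch.

    Images already in the reference batch are passed through the generator
    with the reference style too (identical treatment keeps the corrected
    set on one output manifold). Returns a new ArrayDataset whose batch_ids
    are all the reference id; the manifest, when present, is updated.
    """
    if reference_batch_id not in model.conditions:
        raise KeyError(
            f"reference batch {reference_batch_id!r} unknown; "
            f"registered: {model.conditions.ids()}"
        )
    req = TransformRequest(
        images=dataset.images,
        target_condition=reference_batch_id,
        n_samples=1,
        seed=seed,
    )
    corrected = transform(req, model)[0]
    manifest = None
    if dataset.manifest is not None:
        manifest = dataset.manifest.copy()
        manifest["batch_id"] = reference_batch_id
        if "path" in manifest:
            manifest["path"] = [
                _corrected_name(p, reference_batch_id) for p in manifest["path"]
            ]
    return ArrayDataset(
        images=corrected,
        condition_ids=np.asarray(dataset.condition_ids),
        batch_ids=np.full(len(corrected), reference_batch_id),
        manifest=manifest,
    )


def _corrected_name(path, ref):
    path = str(path)
    stem, dot, suffix = path.rpartition(".")
    return f"{stem}_to_batch{ref}.{suffix}" if dot else f"{path}_to_batch{ref}"
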