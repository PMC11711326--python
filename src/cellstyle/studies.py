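"""Desk-scale reference studies: fixed synthetic conditions, training
configurations and measurements used by the test suite and the acceptance
script.

Two studies are defined. The *perturbation study* trains a one-to-many
model on 32x32 three-channel images of two conditions placed on a line in
embedding space (control, gain 1.0; treated, cytoplasm gain 0.4) and
measures: probe-classifier accuracy of transformed controls against both
targets, output diversity across noise draws, the cycle-reconstruction
error, and the phenotype statistic of the held-out midpoint embedding
(gain 0.7) relative to its trained neighbours. The *batch study* trains a
many-to-many model over three synthetic acquisition batches with trainable
batch embeddings and measures how completely correction transports images
to the reference batch and how much batch impurity within feature clusters
rises.

Problem sizes (image size 32, width 8..32, style 16, noise 8, batch 4,
800/700 iterations) are chosen so each study trains in minutes on one CPU
core while leaving the phenotypes easily separable by a probe classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import (
    FeatureProbeClassifier,
    batch_mixing_scores,
    cluster_impurity,
    coverage,
    extract_features,
    fid_from_features,
)
from .models import ModelConfig, StyleTransferModel
from .synth import (
    BatchEffectSpec,
    PhenotypeSpec,
    make_dataset,
    make_embedding_table,
)
from .training import LossWeights, TrainConfig, fit
from .translate import TransformRequest, batch_correct, transform
from .utils import stream_rng, stream_seed

DESK_MODEL = dict(
    channels=3,
    img_size=32,
    base_width=8,
    max_width=32,
    style_dim=16,
    noise_dim=8,
    dtype="float32",
)

DESK_TRAIN = dict(
    batch_size=4,
    lr_net=1e-3,
    lr_disc=2.5e-4,
    lr_cond=2e-3,
)

# conditions on a line: control (1.0), held-out midpoint (0.7), treated (0.4)
PERTURBATION_SPECS = [
    PhenotypeSpec(condition_id=0, intensity_gain=(1.0, 1.0, 1.0), is_control=True),
    PhenotypeSpec(condition_id=1, intensity_gain=(1.0, 0.7, 0.7)),
    PhenotypeSpec(condition_id=2, intensity_gain=(1.0, 0.4, 0.4)),
]

BATCH_SPECS = [
    BatchEffectSpec(batch_id=0, gain=(1.0, 1.0, 1.0), offset=(0.0, 0.0, 0.0)),
    BatchEffectSpec(batch_id=1, gain=(1.35, 0.75, 1.1), offset=(0.06, 0.0, 0.10),
                    blur_sigma=0.7),
    BatchEffectSpec(batch_id=2, gain=(0.7, 1.25, 0.9), offset=(0.12, 0.06, 0.0)),
]


def phenotype_statistic(images):
    """Mean cytoplasm-channel intensity: the statistic the condition line
    modulates (gain acts on channels 1..C-1)."""
    return float(np.asarray(images)[:, 1:, :, :].mean())


@dataclass
class PerturbationStudyResult:
    model: StyleTransferModel
    history: object
    probe: FeatureProbeClassifier
    metrics: dict = field(default_factory=dict)


def run_perturbation_study(seed=1, iterations=800, n_per_condition=48):
    """Train the one-to-many desk model and measure the study's endpoints."""
    trained_specs = [PERTURBATION_SPECS[0], PERTURBATION_SPECS[2]]
    held_out = PERTURBATION_SPECS[1]
    ds = make_dataset(
        trained_specs,
        [BatchEffectSpec(batch_id=0)],
        n_per_condition,
        size=32,
        channels=3,
        seed=stream_seed(seed, "pert", "data"),
    )
    train = ds.training_set(split="train")
    test = ds.training_set(split="test")

    # the full three-condition line; the midpoint is never trained on
    table = make_embedding_table(
        PERTURBATION_SPECS, dim=8, structure="line",
        seed=stream_seed(seed, "pert", "embeddings"),
    )
    cfg = ModelConfig(modalities={"drug": 8}, **DESK_MODEL)
    model = StyleTransferModel(cfg, n_conditions=2,
                               seed=stream_seed(seed, "pert", "init"))
    # head/condition ids: 0 = control, 1 = treated (gain 0.4)
    model.conditions.add(0, "drug", vector=table[0])
    model.conditions.add(1, "drug", vector=table[2])
    labels = np.where(train.condition_ids == 2, 1, 0)
    train_view = type("View", (), {"images": train.images, "condition_ids": labels})

    tc = TrainConfig(
        mode="one_to_many",
        total_iterations=iterations,
        control_condition=0,
        weights=LossWeights(lambda_adv=2.0),
        seed=stream_seed(seed, "pert", "train"),
        **DESK_TRAIN,
    )
    model, history = fit(train_view, model, tc)

    probe = FeatureProbeClassifier(seed=0).fit(
        train.images, np.where(train.condition_ids == 2, 1, 0)
    )
    test_labels = np.where(test.condition_ids == 2, 1, 0)
    ctrl = test.images[test_labels == 0]
    treated_real = test.images[test_labels == 1]

    out = transform(
        TransformRequest(images=ctrl, target_condition=1, n_samples=2,
                         seed=stream_seed(seed, "pert", "transform")),
        model,
    )
    out_ctrl = transform(
        TransformRequest(images=ctrl, target_condition=0, n_samples=1,
                         seed=stream_seed(seed, "pert", "transform0")),
        model,
    )
    e_ctrl, e_mid, e_strong = table[0], table[1], table[2]
    interp_seed = stream_seed(seed, "pert", "interp")
    g = {
        name: transform(
            TransformRequest(images=ctrl, target_embedding=vec,
                             n_samples=1, seed=interp_seed),
            model,
        )[0]
        for name, vec in
        (("ctrl", e_ctrl), ("mid", e_mid), ("strong", e_strong))
    }

    # cycle property: send transformed images back with the source's own style
    from . import ag

    with ag.no_grad():
        own_style = model.style_from_image(ctrl)
        cycled = model.generate(out[0], own_style).data
    cycle_err = float(np.abs(ctrl - cycled).mean())
    rng = stream_rng(seed, "pert", "pairs")
    perm = rng.permutation(len(test.images))
    random_pair_err = float(
        np.abs(test.images - test.images[perm]).mean()
    )

    real_feats = extract_features(treated_real)
    gen_feats = extract_features(out[0])
    fid_value = fid_from_features(real_feats, gen_feats)
    coverage_value = coverage(real_feats, gen_feats, k=3)

    result = PerturbationStudyResult(model=model, history=history, probe=probe)
    result.metrics = {
        "fid_transformed_vs_real": fid_value,
        "coverage_transformed_vs_real": coverage_value,
        "probe_real_accuracy": probe.score(
            test.images, test_labels
        ),
        "transform_accuracy_treated": float(np.mean(probe.predict(out[0]) == 1)),
        "transform_accuracy_control": float(np.mean(probe.predict(out_ctrl[0]) == 0)),
        "noise_diversity_l1": float(np.abs(out[0] - out[1]).mean()),
        "stat_real_control": phenotype_statistic(ctrl),
        "stat_real_treated": phenotype_statistic(treated_real),
        "stat_generated_control": phenotype_statistic(g["ctrl"]),
        "stat_generated_midpoint": phenotype_statistic(g["mid"]),
        "stat_generated_treated": phenotype_statistic(g["strong"]),
        "cycle_l1": cycle_err,
        "random_pair_l1": random_pair_err,
        "n_train": int(len(train)),
        "n_test": int(len(test)),
        "iterations": int(iterations),
    }
    result.metrics["midpoint_between"] = _between_with_tolerance(
        result.metrics["stat_generated_midpoint"],
        result.metrics["stat_generated_control"],
        result.metrics["stat_generated_treated"],
        tolerance=0.2,
    )
    return result


def _between_with_tolerance(value, a, b, tolerance):
    lo, hi = min(a, b), max(a, b)
    slack = tolerance * (hi - lo)
    return bool(lo - slack <= value <= hi + slack)


@dataclass
class BatchStudyResult:
    model: StyleTransferModel
    history: object
    probe: FeatureProbeClassifier
    metrics: dict = field(default_factory=dict)


def run_batch_study(seed=1, iterations=700, n_per_batch=48):
    """Train the many-to-many batch model and measure correction quality."""
    specs = [PhenotypeSpec(condition_id=0, intensity_gain=(1.0, 1.0, 1.0),
                           is_control=True)]
    ds = make_dataset(
        specs, BATCH_SPECS, n_per_batch, size=32, channels=3,
        seed=stream_seed(seed, "batch", "data"),
    )
    train = ds.training_set(label="batch", split="train")
    test = ds.training_set(label="batch", split="test")

    cfg = ModelConfig(modalities={"batch": 8}, **DESK_MODEL)
    model = StyleTransferModel(cfg, n_conditions=len(BATCH_SPECS),
                               seed=stream_seed(seed, "batch", "init"))
    emb_rng = stream_rng(seed, "batch", "embeddings")
    for spec in BATCH_SPECS:
        model.conditions.add(spec.batch_id, "batch", dim=8, rng=emb_rng)

    tc = TrainConfig(
        mode="many_to_many",
        total_iterations=iterations,
        weights=LossWeights(lambda_adv=2.0),
        seed=stream_seed(seed, "batch", "train"),
        **DESK_TRAIN,
    )
    model, history = fit(train, model, tc)

    probe = FeatureProbeClassifier(seed=0).fit(train.images, train.condition_ids)
    corrected = batch_correct(
        test, 0, model, seed=stream_seed(seed, "batch", "correct")
    )
    feats_before = extract_features(test.images)
    feats_after = extract_features(corrected.images)
    h_before, g_before, _ = cluster_impurity(feats_before, test.batch_ids)
    h_after, g_after, _ = cluster_impurity(feats_after, test.batch_ids)
    asw_b, ilisi_b = batch_mixing_scores(feats_before, test.batch_ids)
    asw_a, ilisi_a = batch_mixing_scores(feats_after, test.batch_ids)

    result = BatchStudyResult(model=model, history=history, probe=probe)
    result.metrics = {
        "probe_real_accuracy": probe.score(test.images, test.condition_ids),
        "corrected_reference_fraction": float(
            np.mean(probe.predict(corrected.images) == 0)
        ),
        "entropy_before": h_before,
        "entropy_after": h_after,
        "gini_before": g_before,
        "gini_after": g_after,
        "silhouette_batch_before": asw_b,
        "silhouette_batch_after": asw_a,
        "ilisi_before": ilisi_b,
        "ilisi_after": ilisi_a,
        "n_train": int(len(train)),
        "n_test": int(len(test)),
        "iterations": int(iterations),
    }
    return result
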