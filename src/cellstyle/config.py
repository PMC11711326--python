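"""Run configuration: strict YAML loading with defaults and round-tripping.

A run config fully determines a training run: data location, model
hyperparameters, loss weights and loop settings, plus one global seed fanned
out to named streams. Unknown keys are rejected by name so typos fail loudly
instead of silently training with defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .models import ModelConfig
from .training import LossWeights, TrainConfig


@dataclass
class RunConfig:
    command: str = "train"
    manifest: str | None = None
    out_dir: str = "run_output"
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=lambda: TrainConfig(mode="many_to_many"))
    weights: LossWeights = field(default_factory=LossWeights)
    label: str = "condition"      # condition | batch
    embedding_dim: int = 8        # synthetic embedding table dimension

    def resolved(self):
        cfg = asdict(self)
        cfg["train"]["weights"] = asdict(self.weights)
        return cfg


def _build(dc_type, payload, context):
    allowed = {f.name for f in fields(dc_type)}
    unknown = set(payload) - allowed
    if unknown:
        raise KeyError(
            f"unknown key(s) {sorted(unknown)} in {context}; allowed: {sorted(allowed)}"
        )
    return dc_type(**payload)


def load_config(path) -> RunConfig:
    """Parse a YAML run config; defaults filled, unknown keys rejected."""
    path = Path(path)
    payload = yaml.safe_load(path.read_text()) or {}
    if not isinstance(payload, dict):
        raise ValueError(f"config root must be a mapping, got {type(payload).__name__}")
    allowed = {f.name for f in fields(RunConfig)}
    unknown = set(payload) - allowed
    if unknown:
        raise KeyError(
            f"unknown key(s) {sorted(unknown)} in config; allowed: {sorted(allowed)}"
        )
    kwargs = dict(payload)
    if "model" in kwargs:
        kwargs["model"] = _build(ModelConfig, kwargs["model"] or {}, "model")
    if "weights" in kwargs:
        kwargs["weights"] = _build(LossWeights, kwargs["weights"] or {}, "weights")
    if "train" in kwargs:
        tr = dict(kwargs["train"] or {})
        if "weights" in tr:
            tr["weights"] = _build(LossWeights, tr["weights"] or {}, "train.weights")
        kwargs["train"] = _build(TrainConfig, tr, "train")
    cfg = _build(RunConfig, kwargs, "config")
    if "weights" in payload and "train" in payload and "weights" not in (payload["train"] or {}):
        cfg.train.weights = cfg.weights
    return cfg


def save_config(cfg: RunConfig, path):
    """Serialize the resolved config next to the run's outputs."""
    Path(path).write_text(yaml.safe_dump(cfg.resolved(), sort_keys=False))
    return path
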