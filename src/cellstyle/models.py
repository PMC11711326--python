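"""The style-transfer model: content encoder, style-conditioned decoder,
style encoder, multi-task discriminator and per-modality condition encoders.

The generator decomposes a cell image into a spatial *content* code (the
cell-specific structure) and a low-dimensional *style* vector (the
perturbation- or batch-specific appearance). Styles are produced by linear
condition encoders acting on the concatenation of a condition embedding and
a Gaussian noise vector, so each condition induces a distribution of styles
rather than a point.

Architecture (input spatial size 96, default widths):

==========  =================================================
encoder     3x3 conv -> 64x96x96; three downsampling residual
            blocks -> 128x48x48 -> 256x24x24 -> 512x12x12;
            two dimension-preserving residual blocks.
decoder     mirror image of the encoder with AdaIN conditioning
            in every residual block; final IN -> LeakyReLU ->
            1x1 conv back to the image channels.
disc/style  shared organization (separate weights): 3x3 conv,
            five downsampling residual blocks to 512x3x3, then
            a 3x3 valid conv to p (sigmoid) or S (linear) units.
==========  =================================================

The same stacks apply to any input whose height and width are divisible by
8 (the three encoder stride-2 stages); the discriminator trunk adapts its
depth to the input size it is built for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import ag, nn
from .ag import Tensor

MODALITIES = ("drug", "crispr", "orf", "batch")


@dataclass
class ModelConfig:
    channels: int = 3
    img_size: int = 96
    base_width: int = 64
    max_width: int = 512
    style_dim: int = 64      # S
    noise_dim: int = 16      # K
    eps: float = nn.IN_EPS
    dtype: str = "float64"   # parameter/activation precision
    # modality -> embedding dimensionality D
    modalities: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.img_size % 8 != 0:
            raise ValueError("img_size must be divisible by 8")
        for m in self.modalities:
            if m not in MODALITIES:
                raise ValueError(f"unknown modality {m!r}; known: {MODALITIES}")

    def widths(self):
        b, m = self.base_width, self.max_width
        return [min(b * 2**i, m) for i in range(4)]


class ConditionTable:
    """Registry mapping condition id -> (modality, embedding vector).

    Non-batch embeddings are fixed arrays; batch embeddings are trainable
    parameters initialized from N(0, 1/D).
    """

    def __init__(self):
        self._entries = {}

    def add(self, condition_id, modality, vector=None, dim=None, rng=None):
        if modality not in MODALITIES:
            raise ValueError(f"unknown modality {modality!r}; known: {MODALITIES}")
        if vector is None:
            if modality != "batch":
                raise ValueError("fixed modalities require an embedding vector")
            if dim is None or rng is None:
                raise ValueError("batch embeddings need dim and rng")
            vec = nn.Parameter(rng.normal(0.0, np.sqrt(1.0 / dim), size=dim))
        else:
            vec = np.asarray(vector, dtype=np.float64)
            if modality == "batch":
                vec = nn.Parameter(vec)
        self._entries[condition_id] = (modality, vec)

    def __contains__(self, condition_id):
        return condition_id in self._entries

    def __len__(self):
        return len(self._entries)

    def ids(self):
        return list(self._entries)

    def modality(self, condition_id):
        return self._entries[condition_id][0]

    def vector(self, condition_id):
        return self._entries[condition_id][1]

    def trainable_parameters(self):
        return [v for _, v in self._entries.values() if isinstance(v, nn.Parameter)]

    def state(self):
        return {
            str(cid): (mod, np.asarray(v.data if isinstance(v, Tensor) else v))
            for cid, (mod, v) in self._entries.items()
        }


class ContentEncoder(nn.Module):
    def __init__(self, cfg: ModelConfig, rng):
        w = cfg.widths()
        self.conv_in = nn.Conv2d(cfg.channels, w[0], 3, rng)
        self.down1 = nn.DownResBlock(w[0], w[1], rng)
        self.down2 = nn.DownResBlock(w[1], w[2], rng)
        self.down3 = nn.DownResBlock(w[2], w[3], rng)
        self.res1 = nn.DownResBlock(w[3], w[3], rng, downsample=False)
        self.res2 = nn.DownResBlock(w[3], w[3], rng, downsample=False)

    def forward(self, x):
        _, _, h, w = x.shape
        if h % 8 or w % 8:
            raise ValueError(f"spatial dims ({h}, {w}) must be divisible by 8")
        h_ = self.conv_in(x)
        h_ = self.down1(h_)
        h_ = self.down2(h_)
        h_ = self.down3(h_)
        h_ = self.res1(h_)
        return self.res2(h_)


class Decoder(nn.Module):
    def __init__(self, cfg: ModelConfig, rng):
        w = cfg.widths()
        s = cfg.style_dim
        self.res1 = nn.UpResBlock(w[3], w[3], s, rng, upsample=False)
        self.res2 = nn.UpResBlock(w[3], w[3], s, rng, upsample=False)
        self.up1 = nn.UpResBlock(w[3], w[2], s, rng)
        self.up2 = nn.UpResBlock(w[2], w[1], s, rng)
        self.up3 = nn.UpResBlock(w[1], w[0], s, rng)
        self.norm_out = nn.InstanceNorm(w[0])
        self.conv_out = nn.Conv2d(w[0], cfg.channels, 1, rng, padding=0)
        self.content_channels = w[3]

    def forward(self, c, style):
        if c.shape[1] != self.content_channels:
            raise ValueError(
                f"content has {c.shape[1]} channels, expected {self.content_channels}"
            )
        h = self.res1(c, style)
        h = self.res2(h, style)
        h = self.up1(h, style)
        h = self.up2(h, style)
        h = self.up3(h, style)
        h = ag.leaky_relu(self.norm_out(h), nn.LEAKY_SLOPE)
        return self.conv_out(h)


class _ConvTrunk(nn.Module):
    """Shared organization of discriminator and style encoder: a 3x3 conv and
    a stack of downsampling residual blocks ending in an out_dim projection."""

    def __init__(self, cfg: ModelConfig, out_dim, rng):
        size = cfg.img_size
        b, m = cfg.base_width, cfg.max_width
        self.conv_in = nn.Conv2d(cfg.channels, b, 3, rng)
        blocks = []
        ch, sp, i = b, size, 0
        # pool down to a 3x3 (or at worst 2x2/4x4) grid before the head
        while sp > 4 and sp % 2 == 0:
            nxt = min(ch * 2, m)
            blocks.append(nn.DownResBlock(ch, nxt, rng))
            ch, sp, i = nxt, sp // 2, i + 1
            if sp == 3:
                break
        self.blocks = blocks
        self.final_spatial = sp
        if sp == 3:
            self.conv_out = nn.Conv2d(ch, out_dim, 3, rng, padding=0)
        else:
            self.conv_out = nn.Conv2d(ch, out_dim, 3, rng, padding=1)
        self.out_dim = out_dim

    def forward(self, x):
        h = self.conv_in(x)
        for blk in self.blocks:
            h = blk(h)
        h = self.conv_out(ag.leaky_relu(h, nn.LEAKY_SLOPE))
        # spatial mean collapses the residual grid when it is not already 1x1
        return h.mean(axis=(2, 3))  # (T, out_dim)


class StyleEncoder(nn.Module):
    def __init__(self, cfg: ModelConfig, rng):
        self.trunk = _ConvTrunk(cfg, cfg.style_dim, rng)

    def forward(self, x):
        return self.trunk(x)  # linear output, unbounded


class Discriminator(nn.Module):
    """Multi-task real/fake discriminator: one sigmoid head per condition."""

    def __init__(self, cfg: ModelConfig, n_conditions, rng):
        if n_conditions < 1:
            raise ValueError("need at least one condition head")
        self.n_conditions = n_conditions
        self.trunk = _ConvTrunk(cfg, n_conditions, rng)

    def forward(self, x):
        return ag.sigmoid(self.trunk(x))  # (T, p), each entry in (0, 1)

    def logits(self, x):
        return self.trunk(x)


class ConditionEncoders(nn.Module):
    """One linear map per modality from [embedding; noise] to the shared
    style space. No activation."""

    def __init__(self, cfg: ModelConfig, rng):
        self.noise_dim = cfg.noise_dim
        self.style_dim = cfg.style_dim
        self._order = sorted(cfg.modalities)
        for mod in self._order:
            setattr(
                self,
                f"f_{mod}",
                nn.Linear(cfg.modalities[mod] + cfg.noise_dim, cfg.style_dim, rng),
            )

    def registered(self):
        return list(self._order)

    def forward(self, modality, e, z):
        if modality not in self._order:
            raise KeyError(
                f"no condition encoder for modality {modality!r}; "
                f"registered: {self._order}"
            )
        e = e if isinstance(e, Tensor) else Tensor(np.atleast_2d(e))
        z = z if isinstance(z, Tensor) else Tensor(np.atleast_2d(z))
        f = getattr(self, f"f_{modality}")
        ez = ag.concat([e, z], axis=1)
        if ez.shape[1] != f.in_features:
            raise ValueError(
                f"embedding+noise length {ez.shape[1]} != expected {f.in_features}"
            )
        return f(ez)


class StyleTransferModel(nn.Module):
    """Full model bundle with checkpointing and seeded initialization."""

    def __init__(self, cfg: ModelConfig, n_conditions, seed=0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.n_conditions = n_conditions
        with nn.param_dtype(cfg.dtype):
            self.encoder = ContentEncoder(cfg, rng)
            self.decoder = Decoder(cfg, rng)
            self.style_encoder = StyleEncoder(cfg, rng)
            self.discriminator = Discriminator(cfg, n_conditions, rng)
            self.condition_encoders = ConditionEncoders(cfg, rng)
        self.conditions = ConditionTable()

    @property
    def dtype(self):
        return np.dtype(self.cfg.dtype)

    # -- the four forward contracts ----------------------------------------
    def encode_content(self, x):
        return self.encoder(_as_tensor(x, self.dtype))

    def decode(self, c, s):
        return self.decoder(c, s)

    def generate(self, x, s):
        return self.decode(self.encode_content(x), s)

    def style_from_image(self, x):
        return self.style_encoder(_as_tensor(x, self.dtype))

    def discriminate(self, x):
        return self.discriminator(_as_tensor(x, self.dtype))

    def encode_condition(self, condition_id, z):
        mod = self.conditions.modality(condition_id)
        vec = self.conditions.vector(condition_id)
        e = vec if isinstance(vec, Tensor) else Tensor(vec.astype(self.dtype))
        e = e.reshape(1, -1)
        z = _as_tensor(z, self.dtype)
        if z.ndim == 1:
            z = z.reshape(1, -1)
        if z.shape[0] > 1:
            e = ag.broadcast_to(e, (z.shape[0], e.shape[1]))
        return self.condition_encoders(mod, e, z)

    def encode_embedding(self, modality, e, z):
        """Style from a raw embedding vector (unseen-condition path)."""
        e = _as_tensor(e, self.dtype)
        if e.ndim == 1:
            e = e.reshape(1, -1)
        z = _as_tensor(z, self.dtype)
        if z.ndim == 1:
            z = z.reshape(1, -1)
        if z.shape[0] > 1 and e.shape[0] == 1:
            e = ag.broadcast_to(e, (z.shape[0], e.shape[1]))
        return self.condition_encoders(modality, e, z)

    def sample_noise(self, rng, n=1):
        return Tensor(
            rng.standard_normal((n, self.cfg.noise_dim)).astype(self.dtype)
        )

    # -- parameter groups ----------------------------------------------------
    def generator_parameters(self):
        return (
            self.encoder.parameters()
            + self.decoder.parameters()
            + self.style_encoder.parameters()
        )

    def condition_parameters(self):
        return self.condition_encoders.parameters() + self.conditions.trainable_parameters()

    # -- persistence ---------------------------------------------------------
    def save(self, path):
        header = {
            "config": asdict(self.cfg),
            "n_conditions": self.n_conditions,
            "condition_ids": [str(c) for c in self.conditions.ids()],
            "condition_modalities": [
                self.conditions.modality(c) for c in self.conditions.ids()
            ],
        }
        arrays = {f"param::{k}": v for k, v in self.state_dict().items()}
        for cid, (mod, vec) in self.conditions.state().items():
            arrays[f"cond::{cid}"] = vec
        arrays["header"] = np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8
        ).copy()
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path):
        with np.load(path) as data:
            header = json.loads(bytes(data["header"]).decode())
            cfg = ModelConfig(**header["config"])
            model = cls(cfg, header["n_conditions"], seed=0)
            state = {
                k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")
            }
            model.load_state_dict(state)
            for cid, mod in zip(header["condition_ids"], header["condition_modalities"]):
                vec = data[f"cond::{cid}"]
                key = int(cid) if cid.lstrip("-").isdigit() else cid
                model.conditions.add(key, mod, vector=vec)
        return model


def he_initialize(model: nn.Module, seed: int) -> nn.Module:
    """Re-draw every conv/linear weight from N(0, 2/fan_in), zero all biases,
    and reset IN affines (gamma 1, beta 0). In-place; returns the model."""
    rng = np.random.default_rng(seed)
    stack = [model]
    while stack:
        mod = stack.pop(0)
        for value in vars(mod).values():
            if isinstance(value, nn.Conv2d):
                k = value.kernel_size
                fan_in = value.in_channels * k * k
                value.weight.data = nn.he_init(
                    rng, fan_in, value.weight.data.shape
                ).astype(value.weight.data.dtype)
                value.bias.data = np.zeros_like(value.bias.data)
            elif isinstance(value, nn.Linear):
                value.weight.data = nn.he_init(
                    rng, value.in_features, value.weight.data.shape
                ).astype(value.weight.data.dtype)
                value.bias.data = np.zeros_like(value.bias.data)
            elif isinstance(value, nn.InstanceNorm):
                value.gamma.data = np.ones_like(value.gamma.data)
                value.beta.data = np.zeros_like(value.beta.data)
            elif isinstance(value, nn.Module):
                stack.append(value)
            elif isinstance(value, (list, tuple)):
                stack.extend(v for v in value if isinstance(v, nn.Module))
    return model


def _as_tensor(x, dtype=np.float64):
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))
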