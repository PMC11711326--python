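"""Adversarial training: losses, condition sampling, augmentation, loop.

Each iteration follows six steps: sample an input pair (always a control
image in one-to-many mode); sample a target condition and two noise vectors;
map both to styles with the condition encoder; update the discriminator on
the adversarial loss plus the R1 gradient penalty on real images; generate
twice to estimate the diversification loss; update the generator, style
encoder and condition encoders on the weighted total objective.

Sign conventions: the adversarial value L_adv = E[log Dis_d(x)] +
E[log(1 - Dis_d'(G(x, s')))] is *ascended* by the discriminator; the
generator minimizes its fake term (saturating) or, by default here,
maximizes log Dis_d'(fake) (the non-saturating variant, which keeps
gradients alive early in training). Style and cycle losses are L1 terms at
their fixed points zero; the diversification loss is a negated L1 and is
non-positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ag
from .ag import Tensor
from .models import StyleTransferModel
from .optim import Adam

PROB_EPS = 1e-7  # clamp for probabilities inside log terms


@dataclass
class LossWeights:
    lambda_adv: float = 1.0
    lambda_sty: float = 1.0
    lambda_cyc: float = 1.0
    lambda_ds_initial: float = 1.0
    lambda_reg: float = 1.0

    def __post_init__(self):
        for name, v in vars(self).items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative number")


@dataclass
class TrainConfig:
    mode: str = "one_to_many"            # or "many_to_many"
    total_iterations: int = 500
    batch_size: int = 8
    lr_net: float = 1e-4                 # generator-side conv networks
    lr_disc: float | None = None         # discriminator (defaults to lr_net)
    lr_cond: float = 1e-6                # condition encoders / batch embeddings
    betas: tuple = (0.0, 0.99)
    flip_probability: float = 0.3
    input_noise_std: float = 0.005
    control_condition: int | None = None
    include_control_target: bool = True
    non_saturating: bool = True
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    checkpoint_every: int | None = None

    def __post_init__(self):
        self.betas = tuple(self.betas)
        if self.mode not in ("one_to_many", "many_to_many"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must lie in [0, 1]")
        if self.mode == "one_to_many" and self.control_condition is None:
            raise ValueError("one_to_many mode requires a control condition")


# ---------------------------------------------------------------------------
# condition sampling
# ---------------------------------------------------------------------------

def sample_target_condition(
    d, mode, rng, n_conditions, control=None, include_control_target=True
):
    """Draw a target condition d' for source condition ``d``.

    one_to_many: the source must be the control; the target is uniform over
    the perturbation pool (optionally including control, so a no-effect
    prediction is a valid target). many_to_many: uniform over all conditions
    except ``d`` itself.
    """
    if mode == "one_to_many":
        if control is None:
            raise ValueError("one_to_many requires a control condition")
        if d != control:
            raise ValueError(
                f"one_to_many sources must be control ({control}), got {d}"
            )
        pool = [j for j in range(n_conditions) if include_control_target or j != control]
        return int(pool[rng.integers(len(pool))])
    if n_conditions < 2:
        raise ValueError("many_to_many requires at least two conditions")
    pool = [j for j in range(n_conditions) if j != d]
    return int(pool[rng.integers(len(pool))])


# ---------------------------------------------------------------------------
# loss terms
# ---------------------------------------------------------------------------

def _clamp_prob(p):
    return ag.clip(p, PROB_EPS, 1.0 - PROB_EPS)


def loss_adversarial(real_probs, fake_probs):
    """The adversarial value E[log Dis_d(x)] + E[log(1 - Dis_d'(fake))].

    The discriminator ascends this; generators use :func:`generator_adv_loss`.
    Probabilities exactly 0 or 1 are clamped at 1e-7 from the boundary.
    """
    real_probs = _clamp_prob(_wrap(real_probs))
    fake_probs = _clamp_prob(_wrap(fake_probs))
    return ag.add(
        ag.tmean(ag.log(real_probs)),
        ag.tmean(ag.log(ag.add(1.0, ag.mul(fake_probs, -1.0)))),
    )


def generator_adv_loss(fake_probs, non_saturating=True):
    """Adversarial term the generator descends."""
    fake_probs = _clamp_prob(_wrap(fake_probs))
    if non_saturating:
        return ag.mul(ag.tmean(ag.log(fake_probs)), -1.0)
    return ag.tmean(ag.log(ag.add(1.0, ag.mul(fake_probs, -1.0))))


def loss_style_recon(target_style, generated, style_encoder):
    """Mean over the batch of the L1 norm || s' - E_sty(G(x, s')) ||_1."""
    pred = style_encoder(generated)
    diff = ag.absolute(ag.add(_wrap(target_style), ag.mul(pred, -1.0)))
    return ag.tmean(ag.tsum(diff, axis=1))


def loss_cycle(x, reconstruction):
    """Mean absolute pixel error between the source and its cycle image."""
    return ag.tmean(ag.absolute(ag.add(_wrap(x), ag.mul(_wrap(reconstruction), -1.0))))


def loss_diversification(out1, out2):
    """Negated mean L1 between two generations of the same condition."""
    return ag.mul(
        ag.tmean(ag.absolute(ag.add(_wrap(out1), ag.mul(_wrap(out2), -1.0)))), -1.0
    )


def gradient_penalty(x, dis_fn):
    """R1 penalty: (1/m) sum_i || d dis_fn(x_i) / d x_i ||_2^2 on real images.

    ``dis_fn`` maps an image tensor to one scalar per image (the active
    discriminator head). The returned scalar remains differentiable with
    respect to the discriminator parameters (double backprop).
    """
    x = _wrap(x)
    xv = Tensor(x.data.copy(), requires_grad=True)
    out = dis_fn(xv)
    (gx,) = ag.grad(ag.tsum(out), [xv], create_graph=True)
    sq = ag.tsum(ag.power(gx, 2.0), axis=tuple(range(1, gx.ndim)))
    return ag.tmean(sq)


def lambda_ds(iteration, total_iterations, initial):
    """Linear decay of the diversification weight, clamped at zero."""
    frac = 1.0 - iteration / total_iterations
    return max(0.0, initial * frac)


def generator_objective(parts, weights: LossWeights, iteration, total_iterations):
    """lambda-weighted total generator loss (Eq-style linear combination)."""
    lds = lambda_ds(iteration, total_iterations, weights.lambda_ds_initial)
    return ag.add(
        ag.add(
            ag.mul(_wrap(parts["adv"]), weights.lambda_adv),
            ag.mul(_wrap(parts["sty"]), weights.lambda_sty),
        ),
        ag.add(
            ag.mul(_wrap(parts["cyc"]), weights.lambda_cyc),
            ag.mul(_wrap(parts["ds"]), lds),
        ),
    )


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(x, flip_probability, noise_std, rng):
    """Independent vertical/horizontal flips per image plus Gaussian noise.

    Operates on a (B, C, H, W) array; labels are unaffected.
    """
    x = np.array(x, copy=True)
    b = x.shape[0]
    vflip = rng.random(b) < flip_probability
    hflip = rng.random(b) < flip_probability
    x[vflip] = x[vflip, :, ::-1, :]
    x[hflip] = x[hflip, :, :, ::-1]
    if noise_std > 0:
        x = x + rng.normal(0.0, noise_std, size=x.shape)
    return x


# ---------------------------------------------------------------------------
# the training iteration
# ---------------------------------------------------------------------------

class Trainer:
    def __init__(self, model: StyleTransferModel, config: TrainConfig):
        self.model = model
        self.config = config
        self.opt_d = Adam(
            model.discriminator.parameters(),
            lr=config.lr_disc if config.lr_disc is not None else config.lr_net,
            betas=config.betas,
        )
        self.opt_g = Adam(
            model.generator_parameters(), lr=config.lr_net, betas=config.betas
        )
        self.opt_f = Adam(
            model.condition_parameters(), lr=config.lr_cond, betas=config.betas
        )
        self.iteration = 0

    def _styles(self, d_target, rng):
        """Styles for the sampled targets with two independent noise draws."""
        z1 = self.model.sample_noise(rng, len(d_target))
        z2 = self.model.sample_noise(rng, len(d_target))
        mods = {self.model.conditions.modality(int(d)) for d in d_target}
        if len(mods) != 1:
            raise ValueError("a batch must target a single modality")
        mod = mods.pop()
        e_t = _embed_batch(self.model, d_target)
        s1 = self.model.condition_encoders(mod, e_t, z1)
        s2 = self.model.condition_encoders(mod, e_t, z2)
        return s1, s2

    def step(self, batch_x, batch_d, rng, ref_x=None, ref_d=None):
        """One iteration. ``(batch_x, batch_d)`` feed the generator (controls
        in one-to-many mode); ``(ref_x, ref_d)`` is the real batch for the
        discriminator's real term, so every active head sees genuine examples
        of its condition. When omitted, the source batch doubles as the real
        batch and targets are drawn with :func:`sample_target_condition`;
        when given, the reference labels *are* the targets."""
        cfg = self.config
        model = self.model
        b = batch_x.shape[0]
        d_src = np.asarray(batch_d, dtype=int)
        if ref_x is None:
            d_tgt = np.array(
                [
                    sample_target_condition(
                        int(d),
                        cfg.mode,
                        rng,
                        model.n_conditions,
                        control=cfg.control_condition,
                        include_control_target=cfg.include_control_target,
                    )
                    for d in d_src
                ]
            )
            real_x, real_d = batch_x, d_src
        else:
            real_x, real_d = ref_x, np.asarray(ref_d, dtype=int)
            d_tgt = real_d
        x = Tensor(np.asarray(batch_x, dtype=model.dtype))
        xr = Tensor(np.asarray(real_x, dtype=model.dtype))
        s1, s2 = self._styles(d_tgt, rng)

        # --- discriminator update ------------------------------------------
        with ag.no_grad():
            fake_d = model.generate(x, s1)
        rows = np.arange(b)
        rrows = np.arange(xr.shape[0])
        real_probs = model.discriminate(xr)[rrows, real_d]
        fake_probs = model.discriminate(Tensor(fake_d.data))[rows, d_tgt]
        adv_value = loss_adversarial(real_probs, fake_probs)

        def head_on_real(img):
            return model.discriminator.logits(img)[rrows, real_d]

        l_reg = gradient_penalty(xr, head_on_real)
        d_loss = ag.add(ag.mul(adv_value, -1.0), ag.mul(l_reg, cfg.weights.lambda_reg))
        self.opt_d.zero_grad()
        model.zero_grad()
        d_loss.backward()
        self.opt_d.step()

        # --- generator / style-encoder / condition-encoder update ----------
        fake1 = model.generate(x, s1)
        with ag.no_grad():
            fake2 = model.generate(x, s2)
        g_fake_probs = model.discriminate(fake1)[rows, d_tgt]
        l_adv_g = generator_adv_loss(g_fake_probs, cfg.non_saturating)
        l_sty = loss_style_recon(s1, fake1, model.style_from_image)
        own_style = model.style_from_image(x)
        cycle_img = model.generate(fake1, own_style)
        l_cyc = loss_cycle(x, cycle_img)
        l_ds = loss_diversification(fake1, Tensor(fake2.data))
        g_loss = generator_objective(
            {"adv": l_adv_g, "sty": l_sty, "cyc": l_cyc, "ds": l_ds},
            cfg.weights,
            self.iteration,
            cfg.total_iterations,
        )
        self.opt_g.zero_grad()
        self.opt_f.zero_grad()
        model.zero_grad()
        g_loss.backward()
        self.opt_g.step()
        self.opt_f.step()

        record = {
            "iteration": self.iteration,
            "L_adv_D": float(-adv_value.item()),
            "L_adv_G": float(l_adv_g.item()),
            "L_sty": float(l_sty.item()),
            "L_cyc": float(l_cyc.item()),
            "L_ds": float(l_ds.item()),
            "L_reg": float(l_reg.item()),
        }
        for name, value in record.items():
            if name != "iteration" and not np.isfinite(value):
                raise FloatingPointError(
                    f"{name} became non-finite at iteration {self.iteration}"
                )
        self.iteration += 1
        return record


def train_step(batch, model, config, rng, trainer=None):
    """One six-step training iteration; returns the loss record."""
    trainer = trainer or Trainer(model, config)
    x, d = batch
    return trainer.step(np.asarray(x), np.asarray(d), rng)


def fit(dataset, model: StyleTransferModel, config: TrainConfig, out_dir=None):
    """Run the full training loop on an in-memory dataset.

    ``dataset`` must expose ``images`` (N, C, H, W in [-1, 1]) and
    ``condition_ids`` (N,). Returns (model, history DataFrame).
    """
    images = np.asarray(dataset.images, dtype=np.float64)
    labels = np.asarray(dataset.condition_ids, dtype=int)
    if len(images) == 0:
        raise ValueError("dataset is empty")
    counts = np.bincount(labels, minlength=model.n_conditions)
    if (counts == 0).any():
        raise ValueError(
            "every condition needs real images (the discriminator heads are "
            f"grounded on them); class counts: {counts.tolist()}"
        )
    if config.mode == "one_to_many":
        pool = np.flatnonzero(labels == config.control_condition)
        if pool.size == 0:
            raise ValueError("one_to_many training requires control images")
    else:
        pool = np.arange(len(images))
    by_condition = {
        c: np.flatnonzero(labels == c) for c in range(model.n_conditions)
    }
    rng = np.random.default_rng(config.seed)
    trainer = Trainer(model, config)
    history = []
    for _ in range(config.total_iterations):
        idx = rng.choice(pool, size=min(config.batch_size, pool.size), replace=True)
        x = augment(
            images[idx], config.flip_probability, config.input_noise_std, rng
        )
        # reference batch: real images of the sampled target conditions, so
        # the discriminator grounds every head it is asked about
        d_tgt = [
            sample_target_condition(
                int(d), config.mode, rng, model.n_conditions,
                control=config.control_condition,
                include_control_target=config.include_control_target,
            )
            for d in labels[idx]
        ]
        ref_idx = np.array([rng.choice(by_condition[d]) for d in d_tgt])
        ref_x = augment(
            images[ref_idx], config.flip_probability, config.input_noise_std, rng
        )
        history.append(
            trainer.step(x, labels[idx], rng, ref_x=ref_x, ref_d=labels[ref_idx])
        )
        if (
            out_dir is not None
            and config.checkpoint_every
            and trainer.iteration % config.checkpoint_every == 0
        ):
            model.save(f"{out_dir}/checkpoint_{trainer.iteration:06d}.npz")
    hist = pd.DataFrame(history)
    if out_dir is not None:
        model.save(f"{out_dir}/model_final.npz")
        hist.to_csv(f"{out_dir}/loss_history.csv", index=False)
    return model, hist


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _embed_batch(model, d_target):
    """Stack condition embeddings for a batch of target ids as one tensor,
    keeping trainable batch embeddings attached to the graph."""
    vecs = [model.conditions.vector(int(d)) for d in d_target]
    if any(isinstance(v, Tensor) and v.requires_grad for v in vecs):
        rowlist = [
            (v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=model.dtype))).reshape(1, -1)
            for v in vecs
        ]
        return ag.concat(rowlist, axis=0)
    return Tensor(
        np.stack(
            [np.asarray(v.data if isinstance(v, Tensor) else v) for v in vecs]
        ).astype(model.dtype)
    )
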