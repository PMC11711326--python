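"""Loss closed forms, condition sampling, augmentation and loop mechanics."""

import numpy as np
import pytest

from cellstyle import ag
from cellstyle.ag import Tensor
from cellstyle.models import ModelConfig, StyleTransferModel
from cellstyle.training import (
    LossWeights,
    TrainConfig,
    Trainer,
    augment,
    fit,
    generator_objective,
    gradient_penalty,
    lambda_ds,
    loss_adversarial,
    loss_cycle,
    loss_diversification,
    loss_style_recon,
    sample_target_condition,
)


class TestConditionSampling:
    def test_many_to_many_is_uniform_over_other_conditions(self):
        rng = np.random.default_rng(0)
        draws = [
            sample_target_condition(0, "many_to_many", rng, 3) for _ in range(10_000)
        ]
        freqs = np.bincount(draws, minlength=3) / len(draws)
        assert freqs[0] == 0.0
        assert abs(freqs[1] - 0.5) < 0.02
        assert abs(freqs[2] - 0.5) < 0.02

    def test_many_to_many_never_returns_source(self):
        rng = np.random.default_rng(1)
        assert all(
            sample_target_condition(2, "many_to_many", rng, 4) != 2
            for _ in range(100_000)
        )

    def test_one_to_many_may_return_control(self):
        rng = np.random.default_rng(2)
        draws = {
            sample_target_condition(0, "one_to_many", rng, 3, control=0)
            for _ in range(200)
        }
        assert 0 in draws and draws == {0, 1, 2}

    def test_one_to_many_rejects_non_control_source(self):
        with pytest.raises(ValueError, match="control"):
            sample_target_condition(
                1, "one_to_many", np.random.default_rng(0), 3, control=0
            )


class TestLossClosedForms:
    def test_adversarial_at_half_probability(self):
        val = loss_adversarial(np.full(8, 0.5), np.full(8, 0.5))
        assert abs(val.item() - 2 * np.log(0.5)) < 1e-12

    def test_adversarial_supremum_near_zero_for_perfect_discriminator(self):
        eps = 1e-6
        val = loss_adversarial(np.full(4, 1 - eps), np.full(4, eps))
        assert abs(val.item()) < 1e-5

    def test_adversarial_matches_hand_summed_expectation(self):
        real = np.array([0.9, 0.6, 0.8])
        fake = np.array([0.2, 0.4])
        expected = np.log(real).mean() + np.log(1 - fake).mean()
        assert abs(loss_adversarial(real, fake).item() - expected) < 1e-12

    def test_boundary_probabilities_are_clamped_finite(self):
        val = loss_adversarial(np.array([1.0, 0.0]), np.array([1.0, 0.0]))
        assert np.isfinite(val.item())

    def test_style_reconstruction_zero_at_fixed_point(self):
        target = Tensor(np.array([[1.0, 2.0]]))
        assert loss_style_recon(target, None, lambda _: target).item() == 0.0

    def test_style_reconstruction_hand_l1(self):
        target = np.array([[1.0, 2.0]])
        pred = Tensor(np.zeros((1, 2)))
        assert loss_style_recon(target, None, lambda _: pred).item() == 3.0

    def test_style_reconstruction_homogeneity(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal((3, 4))
        p = rng.standard_normal((3, 4))
        base = loss_style_recon(t, None, lambda _: Tensor(p)).item()
        scaled = loss_style_recon(3.0 * t, None, lambda _: Tensor(3.0 * p)).item()
        assert abs(scaled - 3.0 * base) < 1e-10

    def test_cycle_zero_for_identity_and_hand_value(self):
        x = np.zeros((2, 1, 2, 2))
        assert loss_cycle(x, x).item() == 0.0
        assert abs(loss_cycle(x, x + 0.5).item() - 0.5) < 1e-12
        rng = np.random.default_rng(0)
        assert loss_cycle(rng.standard_normal((2, 1, 2, 2)), x).item() >= 0.0

    def test_diversification_zero_for_equal_styles_and_hand_value(self):
        x = np.random.default_rng(0).standard_normal((2, 1, 3, 3))
        assert loss_diversification(x, x).item() == 0.0
        assert abs(loss_diversification(x, x + 0.2).item() + 0.2) < 1e-12
        assert loss_diversification(x, x + 1.7).item() <= 0.0


class TestGradientPenalty:
    def test_locally_constant_discriminator_has_zero_penalty(self):
        x = np.random.default_rng(0).standard_normal((3, 2, 2, 2))
        val = gradient_penalty(x, lambda t: ag.tsum(ag.mul(t, 0.0), axis=(1, 2, 3)))
        assert val.item() == 0.0

    def test_linear_discriminator_gives_weight_norm(self):
        rng = np.random.default_rng(1)
        w = rng.standard_normal((2, 2, 2))
        x = rng.standard_normal((4, 2, 2, 2))

        def dis(t):
            return ag.tsum(ag.mul(t, Tensor(w[None])), axis=(1, 2, 3))

        assert abs(gradient_penalty(x, dis).item() - (w**2).sum()) < 1e-10

    def test_matches_finite_difference_gradients_on_tiny_net(self):
        from cellstyle import nn

        rng = np.random.default_rng(2)
        conv = nn.Conv2d(1, 1, 3, rng)
        x0 = rng.standard_normal((1, 1, 4, 4))

        def head(t):
            return ag.tsum(ag.sigmoid(conv(t)), axis=(1, 2, 3))

        # compare the input-gradient the penalty squares with finite differences
        xv = Tensor(x0.copy(), requires_grad=True)
        (gx,) = ag.grad(ag.tsum(head(xv)), [xv])
        num = np.zeros_like(x0)
        eps = 1e-6
        for idx in np.ndindex(x0.shape):
            xp, xm = x0.copy(), x0.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num[idx] = (
                ag.tsum(head(Tensor(xp))).item() - ag.tsum(head(Tensor(xm))).item()
            ) / (2 * eps)
        np.testing.assert_allclose(gx.data, num, atol=1e-4)
        assert abs(gradient_penalty(x0, head).item() - (num**2).sum()) < 1e-4


class TestGeneratorObjective:
    def test_lambda_ds_linear_decay(self):
        assert lambda_ds(0, 100, 2.0) == 2.0
        assert lambda_ds(50, 100, 2.0) == 1.0
        assert lambda_ds(100, 100, 2.0) == 0.0
        vals = [lambda_ds(t, 100, 2.0) for t in range(101)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_unit_parts_and_weights_sum_to_four_at_start(self):
        parts = {k: Tensor(np.array(1.0)) for k in ("adv", "sty", "cyc", "ds")}
        total = generator_objective(parts, LossWeights(), 0, 100)
        assert abs(total.item() - 4.0) < 1e-12

    def test_weighted_sum_matches_hand_arithmetic(self):
        parts = {
            "adv": Tensor(np.array(0.3)),
            "sty": Tensor(np.array(-1.2)),
            "cyc": Tensor(np.array(2.0)),
            "ds": Tensor(np.array(-0.4)),
        }
        w = LossWeights(lambda_adv=2.0, lambda_sty=0.5, lambda_cyc=1.5,
                        lambda_ds_initial=1.0, lambda_reg=1.0)
        expected = 2.0 * 0.3 + 0.5 * -1.2 + 1.5 * 2.0 + 0.75 * -0.4
        assert abs(generator_objective(parts, w, 25, 100).item() - expected) < 1e-12

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            LossWeights(lambda_cyc=-0.1)


class TestAugmentation:
    def test_identity_when_disabled(self):
        x = np.random.default_rng(0).standard_normal((5, 2, 4, 4))
        out = augment(x, flip_probability=0.0, noise_std=0.0,
                      rng=np.random.default_rng(1))
        assert np.array_equal(out, x)

    def test_certain_flips_are_involutions(self):
        x = np.random.default_rng(0).standard_normal((3, 2, 4, 4))
        once = augment(x, 1.0, 0.0, np.random.default_rng(1))
        twice = augment(once, 1.0, 0.0, np.random.default_rng(2))
        assert np.allclose(twice, x)

    def test_flip_frequency_matches_probability(self):
        rng = np.random.default_rng(3)
        x = np.zeros((10_000, 1, 2, 1))
        x[:, 0, 0, 0] = 1.0  # vertical flip moves the marker
        out = augment(x, 0.3, 0.0, rng)
        flipped = (out[:, 0, 1, 0] == 1.0).mean()
        assert abs(flipped - 0.3) < 0.02


class TestTrainStep:
    @pytest.fixture()
    def setup(self, tiny_model, rng):
        x = rng.standard_normal((4, 3, 16, 16)) * 0.2
        d = np.array([0, 0, 1, 1])
        return tiny_model, x, d

    def test_smoke_step_records_finite_losses(self, setup):
        model, x, d = setup
        cfg = TrainConfig(mode="many_to_many", total_iterations=10, batch_size=4,
                          lr_net=1e-4, lr_cond=1e-4, seed=0)
        rec = Trainer(model, cfg).step(x, d, np.random.default_rng(0))
        for key in ("L_adv_D", "L_adv_G", "L_sty", "L_cyc", "L_ds", "L_reg"):
            assert np.isfinite(rec[key])
        assert rec["L_sty"] >= 0 and rec["L_cyc"] >= 0 and rec["L_ds"] <= 0

    def test_parameters_move_with_nonzero_learning_rate(self, setup):
        model, x, d = setup
        cfg = TrainConfig(mode="many_to_many", total_iterations=10, batch_size=4,
                          lr_net=1e-3, lr_cond=1e-3, seed=0)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        Trainer(model, cfg).step(x, d, np.random.default_rng(0))
        moved = [k for k, v in model.state_dict().items()
                 if not np.array_equal(before[k], v)]
        assert any("decoder" in k for k in moved)
        assert any("discriminator" in k for k in moved)

    def test_zero_learning_rate_keeps_parameters_bitwise(self, setup):
        model, x, d = setup
        cfg = TrainConfig(mode="many_to_many", total_iterations=10, batch_size=4,
                          lr_net=0.0, lr_cond=0.0, seed=0)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        Trainer(model, cfg).step(x, d, np.random.default_rng(0))
        for k, v in model.state_dict().items():
            assert np.array_equal(before[k], v), k


def _tiny_dataset(rng, n=12):
    images = rng.standard_normal((n, 3, 16, 16)) * 0.1
    images[n // 2:, 1:] += 0.4  # second condition is brighter
    labels = np.array([0] * (n // 2) + [1] * (n // 2))
    return type("DS", (), {"images": images, "condition_ids": labels})


class TestFit:
    def _model(self):
        cfg = ModelConfig(channels=3, img_size=16, base_width=4, max_width=16,
                          style_dim=8, noise_dim=4, modalities={"drug": 6})
        model = StyleTransferModel(cfg, n_conditions=2, seed=3)
        gen = np.random.default_rng(5)
        for cid in (0, 1):
            model.conditions.add(cid, "drug", vector=gen.standard_normal(6))
        return model

    def test_history_length_and_reproducibility(self, rng):
        ds = _tiny_dataset(rng)
        cfg = TrainConfig(mode="many_to_many", total_iterations=5, batch_size=4,
                          lr_net=1e-4, lr_cond=1e-4, seed=11)
        _, hist1 = fit(ds, self._model(), cfg)
        _, hist2 = fit(ds, self._model(), cfg)
        assert len(hist1) == 5
        assert abs(hist1["L_cyc"].iloc[-1] - hist2["L_cyc"].iloc[-1]) <= 1e-6

    def test_empty_condition_class_is_reported_with_counts(self, rng):
        ds = _tiny_dataset(rng)
        ds.condition_ids = np.zeros(len(ds.images), dtype=int)
        cfg = TrainConfig(mode="many_to_many", total_iterations=2, batch_size=4,
                          seed=0)
        with pytest.raises(ValueError, match="class counts"):
            fit(ds, self._model(), cfg)

    def test_discriminator_alone_improves_its_objective(self, rng):
        """With the generator frozen, discriminator training should raise the
        adversarial value (trend over the run, not per step)."""
        ds = _tiny_dataset(rng)
        model = self._model()
        cfg = TrainConfig(mode="many_to_many", total_iterations=50, batch_size=4,
                          lr_net=0.0, lr_disc=1e-3, lr_cond=0.0, seed=2)
        _, hist = fit(ds, model, cfg)
        # L_adv_D = -(adversarial value); early mean should exceed late mean
        early = hist["L_adv_D"].iloc[:10].mean()
        late = hist["L_adv_D"].iloc[-10:].mean()
        assert late < early
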