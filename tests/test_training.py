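"""Loss oracles, mask dropout, augmentation contracts, and the training
loops' wiring."""

import math

import numpy as np
import pytest

from clickseg.training import (
    AugmentConfig,
    LossConfig,
    TrainingConfig,
    apply_mask_dropout,
    augment,
    bce_loss,
    composite_loss,
    dice_loss,
    train_baseline,
    train_initial,
    train_refinement,
    _composite_grad_wrt_logits,
    _train_step,
)
from clickseg import nn
from clickseg.volumes import ProbabilityVolume

from conftest import tiny_net_cfg


def _vol(x):
    return np.asarray(x, dtype=np.float64)


class TestDiceLoss:
    def test_perfect_binary_prediction_is_near_zero(self, rng):
        g = (rng.random((8, 8, 8)) > 0.7).astype(np.float64)
        assert dice_loss(g, g) < 1e-6

    def test_both_empty_is_exactly_zero(self):
        z = np.zeros((8, 8, 8))
        assert dice_loss(z, z) == 0.0  # eps/eps cancels exactly

    def test_uniform_half_hand_value(self):
        # 8 voxels at p=0.5, 4 foreground: 1 - (2*2 + eps)/(4 + 4 + eps)
        p = np.full(8, 0.5)
        g = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        eps = 1e-5
        assert dice_loss(p, g, eps) == pytest.approx(1 - (4 + eps) / (8 + eps))

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(10):
            p = rng.random((6, 6, 6))
            g = (rng.random((6, 6, 6)) > 0.5).astype(float)
            assert 0.0 <= dice_loss(p, g) <= 1.0


class TestBCELoss:
    def test_uniform_half_is_n_log_two(self, rng):
        g = (rng.random((8, 8, 8)) > 0.5).astype(float)
        n = g.size
        assert bce_loss(np.full(g.shape, 0.5), g) == pytest.approx(
            n * math.log(2.0), abs=1e-9
        )

    def test_single_voxel_hand_value(self):
        # g=1, p=0.25 -> -ln 0.25; embed in a minimal volume
        p = np.full((8, 8, 8), 0.5)
        g = np.zeros((8, 8, 8))
        base = bce_loss(p, g)
        p[0, 0, 0] = 0.25
        g[0, 0, 0] = 1.0
        delta = bce_loss(p, g) - (base - math.log(2.0))
        assert delta == pytest.approx(-math.log(0.25), abs=1e-9)

    def test_near_perfect_prediction_is_near_zero(self, rng):
        g = (rng.random((8, 8, 8)) > 0.5).astype(float)
        assert bce_loss(g, g) < 1e-3  # only the clip delta remains
        assert bce_loss(g, g) >= 0.0

    def test_mean_reduction_divides_by_voxels(self, rng):
        p = rng.random((8, 8, 8))
        g = (rng.random((8, 8, 8)) > 0.5).astype(float)
        assert bce_loss(p, g, "mean") == pytest.approx(bce_loss(p, g) / p.size)


class TestCompositeLoss:
    def test_composite_is_the_sum_of_components(self, rng):
        for _ in range(5):
            p = rng.random((6, 6, 6))
            g = (rng.random((6, 6, 6)) > 0.5).astype(float)
            assert composite_loss(p, g) == pytest.approx(
                dice_loss(p, g) + bce_loss(p, g), rel=1e-12
            )

    def test_both_empty_is_near_zero(self):
        z = np.zeros((8, 8, 8))
        assert composite_loss(z, z) == pytest.approx(0.0, abs=1e-3)

    def test_gradient_matches_finite_differences(self, rng):
        """The analytic d(loss)/d(logit) used by the optimizer steps."""
        z = rng.standard_normal((5, 5, 5))
        g = (rng.random((5, 5, 5)) > 0.5).astype(np.float64)
        p = 1.0 / (1.0 + np.exp(-z))
        grad = _composite_grad_wrt_logits(p, g, LossConfig())
        for idx in [(0, 0, 0), (2, 3, 4), (4, 4, 4)]:
            h = 1e-6
            zp = z.copy(); zp[idx] += h
            zm = z.copy(); zm[idx] -= h
            fd = (
                composite_loss(1 / (1 + np.exp(-zp)), g)
                - composite_loss(1 / (1 + np.exp(-zm)), g)
            ) / (2 * h)
            assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestMaskDropout:
    def test_zero_probability_never_drops(self, rng):
        prev = ProbabilityVolume(rng.random((8, 8, 8)).astype(np.float32))
        for _ in range(20):
            assert apply_mask_dropout(prev, 0.0, rng) is prev

    def test_certain_drop_gives_neutral_half_volume(self, rng):
        prev = ProbabilityVolume(rng.random((8, 8, 8)).astype(np.float32))
        out = apply_mask_dropout(prev, 1.0, rng)
        assert (out.data == 0.5).all()

    def test_invalid_probability_rejected(self, rng):
        prev = ProbabilityVolume(np.zeros((8, 8, 8), np.float32))
        with pytest.raises(ValueError):
            apply_mask_dropout(prev, 1.5, rng)


class TestAugment:
    def _identity_cfg(self):
        return AugmentConfig(p_affine=0.0, p_mirror=0.0, p_intensity=0.0)

    def test_all_probabilities_zero_is_identity(self, tiny_phantom, rng):
        pair, gt = augment(tiny_phantom.pair, tiny_phantom.gt, rng,
                           self._identity_cfg())
        np.testing.assert_array_equal(pair.ct.data, tiny_phantom.pair.ct.data)
        np.testing.assert_array_equal(pair.pet.data, tiny_phantom.pair.pet.data)
        np.testing.assert_array_equal(gt.data, tiny_phantom.gt.data)

    def test_mask_stays_binary_under_forced_affine(self, tiny_phantom, rng):
        cfg = AugmentConfig(p_affine=1.0, p_mirror=1.0, p_intensity=0.0,
                            translate_vox=3.0)
        _, gt = augment(tiny_phantom.pair, tiny_phantom.gt, rng, cfg)
        assert set(np.unique(gt.data)) <= {0, 1}

    def test_pet_channel_never_gets_intensity_augmentation(self, tiny_phantom, rng):
        cfg = AugmentConfig(p_affine=0.0, p_mirror=0.0, p_intensity=1.0)
        pair, _ = augment(tiny_phantom.pair, tiny_phantom.gt, rng, cfg)
        np.testing.assert_array_equal(pair.pet.data, tiny_phantom.pair.pet.data)
        assert not np.array_equal(pair.ct.data, tiny_phantom.pair.ct.data)

    def test_same_mirror_hits_image_and_mask(self, tiny_phantom, rng):
        cfg = AugmentConfig(p_affine=0.0, p_mirror=1.0, p_intensity=0.0)
        pair, gt = augment(tiny_phantom.pair, tiny_phantom.gt, rng, cfg)
        axes = (0, 1, 2)  # p_mirror=1 flips every axis
        np.testing.assert_array_equal(gt.data, np.flip(tiny_phantom.gt.data, axes))
        np.testing.assert_array_equal(
            pair.ct.data, np.flip(tiny_phantom.pair.ct.data, axes)
        )
        np.testing.assert_array_equal(
            pair.pet.data, np.flip(tiny_phantom.pair.pet.data, axes)
        )


class TestTrainingLoops:
    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_initial([], TrainingConfig.desk_scale())

    def test_refinement_requires_two_channel_first_stage(self, tiny_dataset, tiny_nets):
        with pytest.raises(ValueError, match="2-channel"):
            train_refinement(tiny_dataset, tiny_nets[5], TrainingConfig.desk_scale())

    def test_step_loss_equals_composite_on_reported_probabilities(self, tiny_phantom):
        from clickseg.networks import build_network, input_stack

        net = build_network(tiny_net_cfg(2), seed=0)
        opt = nn.AdamW(net.parameters(), lr=1e-3)
        cfg = TrainingConfig.desk_scale()
        x = input_stack(tiny_phantom.pair, mode="initial")
        loss, p = _train_step(net, opt, x, tiny_phantom.gt.data, cfg)
        assert loss == pytest.approx(
            composite_loss(p.astype(np.float64), tiny_phantom.gt.data), rel=1e-5
        )

    def test_loss_descends_on_a_single_sample(self, tiny_phantom):
        from clickseg.networks import build_network, input_stack

        net = build_network(tiny_net_cfg(2), seed=0)
        opt = nn.AdamW(net.parameters(), lr=3e-3)
        cfg = TrainingConfig.desk_scale()
        x = input_stack(tiny_phantom.pair, mode="initial")
        losses = [
            _train_step(net, opt, x, tiny_phantom.gt.data, cfg)[0] for _ in range(40)
        ]
        assert losses[-1] < losses[0] * 0.5
        assert losses[-1] < min(losses[:5])

    def test_refinement_training_leaves_initial_frozen(self, tiny_dataset):
        cfg = TrainingConfig.desk_scale(seed=3, max_epochs=1, patience=1,
                                        interactions_range=(1, 2))
        init = train_initial(tiny_dataset, cfg, net_cfg=tiny_net_cfg(2))
        before = {k: p.data.copy() for k, p in init.net.named_parameters().items()}
        res = train_refinement(tiny_dataset, init.net, cfg, net_cfg=tiny_net_cfg(5))
        for k, p in init.net.named_parameters().items():
            np.testing.assert_array_equal(p.data, before[k])
        assert res.counters["n_events"] > 0

    def test_seeded_initial_training_is_reproducible(self, tiny_dataset):
        cfg = TrainingConfig.desk_scale(seed=9, max_epochs=1, patience=1)
        a = train_initial(tiny_dataset, cfg, net_cfg=tiny_net_cfg(2))
        b = train_initial(tiny_dataset, cfg, net_cfg=tiny_net_cfg(2))
        assert a.history == b.history
        for pa, pb in zip(a.net.parameters(), b.net.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_baseline_click_free_limit_is_non_interactive(self, tiny_dataset):
        cfg = TrainingConfig.desk_scale(seed=2, max_epochs=1, patience=1,
                                        click_free_fraction=1.0)
        res = train_baseline(tiny_dataset, cfg, net_cfg=tiny_net_cfg(4))
        assert res.counters["n_click_free"] == res.counters["n_iterations"]
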