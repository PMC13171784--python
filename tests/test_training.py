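"""Losses, schedules, boosting, augmentation and the training driver."""

import numpy as np
import pytest

import hepaseg as hs
from hepaseg.training import (
    AugmentConfig, BoostPolicy, ClassWeights, LRScheduleParams, LossWeights,
    TrainConfig, VESSEL_LOSS_WEIGHTS, boost_weights, composite_loss,
    cosine_lr, cross_validate, flip_pair, rotate_pair, train_model,
)
from hepaseg.unet_models import UNetConfig, predict_labels
from hepaseg.wsi_patching import DatasetSplit


class TestCosineLR:
    def test_endpoints_and_midpoint(self):
        p = LRScheduleParams(eta_max=5e-4, eta_min=0.0, T=250)
        assert cosine_lr(0, p) == pytest.approx(5e-4)
        assert cosine_lr(250, p) == pytest.approx(0.0, abs=1e-12)
        assert cosine_lr(125, p) == pytest.approx(2.5e-4)

    def test_monotone_non_increasing(self):
        p = LRScheduleParams(eta_max=1e-3, eta_min=1e-5, T=100)
        lrs = [cosine_lr(t, p) for t in range(101)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        assert lrs[-1] == pytest.approx(1e-5)

    def test_epoch_outside_range_rejected(self):
        with pytest.raises(ValueError):
            cosine_lr(300, LRScheduleParams(T=250))


class TestBoostWeights:
    @pytest.mark.parametrize("dice,w0,expected", [
        (0.25, 1.0, 1.3),    # below the first threshold
        (0.30, 1.0, 1.2),    # half-open interval: boundary joins the upper band
        (0.45, 1.0, 1.2),
        (0.55, 1.0, 1.1),
        (0.69, 2.0, 2.2),
        (0.70, 1.0, 1.0),    # at/above the top threshold: unchanged
        (0.75, 2.0, 2.0),
    ])
    def test_factor_bands(self, dice, w0, expected):
        w = ClassWeights(np.array([1.0, w0]))
        out = boost_weights(w, {1: dice}, BoostPolicy(), epoch=15)
        assert out.values[1] == pytest.approx(expected)

    def test_background_never_boosted(self):
        w = ClassWeights(np.ones(3))
        out = boost_weights(w, {1: 0.1, 2: 0.1}, BoostPolicy(), epoch=15)
        assert out.values[0] == 1.0
        assert np.allclose(out.values[1:], 1.3)

    def test_weights_never_decrease_and_identity_above_07(self, rng):
        w = ClassWeights(rng.uniform(0.5, 3.0, size=5))
        dice = {c: float(rng.uniform(0, 1)) for c in range(1, 5)}
        out = boost_weights(w, dice, BoostPolicy(), epoch=30)
        assert (out.values >= w.values - 1e-12).all()
        all_good = boost_weights(w, {c: 0.9 for c in range(1, 5)},
                                 BoostPolicy(), epoch=30)
        assert np.allclose(all_good.values, w.values)

    def test_compounding_for_stuck_class(self):
        """A class stuck below Dice 0.3 compounds ×1.3 per period: after
        three boost epochs its weight is 1.3³ = 2.197."""
        w = ClassWeights(np.ones(2))
        for epoch in (15, 30, 45):
            w = boost_weights(w, {1: 0.2}, BoostPolicy(), epoch=epoch)
        assert w.values[1] == pytest.approx(1.3 ** 3)

    def test_cap_bounds_weights(self):
        w = ClassWeights(np.array([1.0, 9.5]))
        out = boost_weights(w, {1: 0.1}, BoostPolicy(), epoch=15)
        assert out.values[1] == pytest.approx(10.0)

    def test_missing_class_rejected(self):
        with pytest.raises(KeyError):
            boost_weights(ClassWeights(np.ones(3)), {1: 0.5}, BoostPolicy(),
                          epoch=15)

    def test_off_period_epoch_rejected(self):
        with pytest.raises(ValueError):
            boost_weights(ClassWeights(np.ones(2)), {1: 0.5}, BoostPolicy(),
                          epoch=7)


class TestCompositeLoss:
    def _one_hot(self, grid, C):
        return np.eye(C)[grid].transpose(2, 0, 1)

    def test_perfect_hard_prediction_is_near_zero(self, rng):
        grid = rng.integers(0, 3, (16, 16))
        probs = self._one_hot(grid, 3)
        loss = composite_loss(probs, grid, ClassWeights.uniform(3),
                              VESSEL_LOSS_WEIGHTS)
        assert 0 <= loss < 1e-3

    def test_pure_ce_with_uniform_weights_is_plain_cross_entropy(self, rng):
        grid = rng.integers(0, 2, (8, 8))
        probs = np.clip(rng.random((2, 8, 8)), 0.05, 0.95)
        probs /= probs.sum(axis=0)
        loss = composite_loss(probs, grid, ClassWeights.uniform(2),
                              LossWeights(1.0, 0.0, 0.0))
        p_t = np.take_along_axis(probs, grid[None], axis=0)[0]
        assert loss == pytest.approx(float(-np.log(p_t).mean()), rel=1e-6)

    def test_pure_dice_on_complement_prediction_approaches_one(self):
        grid = np.zeros((10, 10), np.int64)
        grid[:5] = 1
        probs = self._one_hot(1 - grid, 2)  # predict the complement
        loss = composite_loss(probs, grid, ClassWeights.uniform(2),
                              LossWeights(0.0, 1.0, 0.0))
        assert loss == pytest.approx(1.0, abs=1e-3)

    def test_invariant_under_joint_geometric_transform(self, rng):
        """Flipping scores and targets together leaves the loss unchanged."""
        grid = rng.integers(0, 3, (12, 12))
        probs = rng.random((3, 12, 12))
        probs /= probs.sum(axis=0)
        cw = ClassWeights(np.array([1.0, 2.0, 0.5]))
        base = composite_loss(probs, grid, cw, VESSEL_LOSS_WEIGHTS)
        for axis in (1, 2):
            flipped = composite_loss(np.flip(probs, axis=axis).copy(),
                                     np.flip(grid, axis=axis - 1).copy(),
                                     cw, VESSEL_LOSS_WEIGHTS)
            assert flipped == pytest.approx(base, rel=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        probs = rng.random((2, 8, 8))
        with pytest.raises(ValueError):
            composite_loss(probs, np.zeros((9, 9), np.int64),
                           ClassWeights.uniform(2), VESSEL_LOSS_WEIGHTS)

    def test_loss_weights_validated(self):
        with pytest.raises(ValueError):
            LossWeights(0.5, 0.6, 0.2)
        with pytest.raises(ValueError):
            LossWeights(-0.2, 1.0, 0.2)


class TestAugment:
    def test_rotating_180_twice_is_identity(self, rng):
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        grid = rng.integers(0, 5, (16, 16)).astype(np.uint8)
        i1, g1 = rotate_pair(img, grid, 180)
        i2, g2 = rotate_pair(i1, g1, 180)
        assert np.array_equal(i2, img) and np.array_equal(g2, grid)

    def test_flips_preserve_per_class_pixel_counts(self, rng):
        grid = rng.integers(0, 5, (16, 16)).astype(np.uint8)
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        for axis in (0, 1):
            _, flipped = flip_pair(img, grid, axis)
            assert np.array_equal(np.bincount(flipped.ravel(), minlength=5),
                                  np.bincount(grid.ravel(), minlength=5))

    def test_oblique_rotation_invents_no_labels(self, rng):
        grid = (rng.integers(0, 2, (32, 32)) * 4).astype(np.uint8)  # {0, 4}
        img = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        _, rotated = rotate_pair(img, grid, 30)
        assert set(np.unique(rotated)) <= {0, 4}

    def test_joint_transform_keeps_pair_aligned(self, rng):
        """Image and mask receive the same geometry: a marker painted into
        both stays colocated through the random augmentation."""
        img = np.zeros((32, 32, 3), np.uint8)
        grid = np.zeros((32, 32), np.uint8)
        img[4:8, 20:26] = 255
        grid[4:8, 20:26] = 1
        mask = hs.LabelMask(grid, hs.LOBULE_PALETTE, 1.0)
        cfg = AugmentConfig(intensity=False)
        for seed in range(6):
            aug_img, aug_mask = hs.augment(img, mask, cfg, seed)
            assert np.array_equal(aug_img[..., 0] > 127, aug_mask.grid == 1)

    def test_deterministic_under_seed(self, rng):
        img = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        mask = hs.LabelMask(rng.integers(0, 2, (32, 32)).astype(np.uint8),
                            hs.LOBULE_PALETTE, 1.0)
        a_img, a_mask = hs.augment(img, mask, AugmentConfig(), 99)
        b_img, b_mask = hs.augment(img, mask, AugmentConfig(), 99)
        assert np.array_equal(a_img, b_img)
        assert np.array_equal(a_mask.grid, b_mask.grid)


def _tiny_pairs(rng, n=2, size=32):
    pairs = []
    for _ in range(n):
        grid = np.zeros((size, size), np.uint8)
        r, c = rng.integers(6, size - 12, 2)
        grid[r:r + 8, c:c + 8] = 1
        img = np.full((size, size, 3), 220, np.uint8)
        img[grid == 1] = (40, 40, 200)
        pairs.append((img, hs.LabelMask(grid, hs.LOBULE_PALETTE, 1.0)))
    return pairs


class TestTrainModel:
    def test_single_patch_overfit_recovers_its_own_mask(self, rng):
        pairs = _tiny_pairs(rng, n=1)
        split = DatasetSplit([], [[0], [0]], seed=0)
        cfg = TrainConfig(model=UNetConfig(base_channels=8, depth=2,
                                           n_classes=2),
                          epochs=100, batch_size=1,
                          lr=LRScheduleParams(3e-3, 0.0, 100), patience=99,
                          augment=None, seed=0)
        model, history = train_model(pairs, split, cfg,
                                     loss_weights=hs.LOBULE_LOSS_WEIGHTS,
                                     fold=1)
        pred = predict_labels(model, pairs[0][0], hs.LOBULE_PALETTE, 1.0)
        assert hs.dice(pred.grid == 1, pairs[0][1].grid == 1) > 0.99
        # history records the full schedule state
        for col in ("train_loss", "val_loss", "lr", "val_dice_1",
                    "class_weight_1"):
            assert col in history.columns

    def test_empty_split_rejected(self, rng):
        pairs = _tiny_pairs(rng)
        cfg = TrainConfig(model=UNetConfig(base_channels=2, depth=2,
                                           n_classes=2), epochs=2,
                          augment=None)
        with pytest.raises(ValueError):
            train_model(pairs, DatasetSplit([], [[], [0, 1]], seed=0), cfg,
                        fold=1)

    def test_early_stopping_after_patience_stagnant_epochs(self, rng):
        """With a divergent learning rate the validation loss worsens after
        the first epoch and training stops once `patience` epochs pass
        without improvement."""
        pairs = _tiny_pairs(rng)
        split = DatasetSplit([], [[0], [1]], seed=0)
        cfg = TrainConfig(model=UNetConfig(base_channels=2, depth=2,
                                           n_classes=2),
                          epochs=12, batch_size=1,
                          lr=LRScheduleParams(5.0, 4.9, 12), patience=2,
                          augment=None, seed=0)
        _, history = train_model(pairs, split, cfg,
                                 loss_weights=hs.LOBULE_LOSS_WEIGHTS, fold=1)
        assert len(history) < 12
        best_epoch = int(history["val_loss"].idxmin()) + 1
        assert len(history) == best_epoch + cfg.patience

    def test_learning_rate_sequence_is_data_independent(self, rng):
        pairs = _tiny_pairs(rng)
        split = DatasetSplit([], [[0], [1]], seed=0)
        cfg = TrainConfig(model=UNetConfig(base_channels=2, depth=2,
                                           n_classes=2),
                          epochs=4, batch_size=1,
                          lr=LRScheduleParams(1e-3, 0.0, 4), patience=3,
                          augment=None, seed=0)
        _, history = train_model(pairs, split, cfg,
                                 loss_weights=hs.LOBULE_LOSS_WEIGHTS, fold=1)
        expected = [cosine_lr(t, cfg.lr) for t in range(len(history))]
        assert np.allclose(history["lr"], expected)


class TestCrossValidate:
    def test_each_fold_trained_and_aggregated_as_mean_sd(self, rng):
        pairs = _tiny_pairs(rng, n=4)
        split = DatasetSplit([], [[0, 1], [2, 3]], seed=0)
        cfg = TrainConfig(model=UNetConfig(base_channels=2, depth=2,
                                           n_classes=2),
                          epochs=2, batch_size=2,
                          lr=LRScheduleParams(1e-3, 0.0, 2), patience=1,
                          augment=None, seed=0)
        reports, aggregate = cross_validate(pairs, split, cfg,
                                            loss_weights=hs.LOBULE_LOSS_WEIGHTS)
        assert [r["fold"] for r in reports] == [0, 1]
        for c, (mean, sd) in aggregate.items():
            vals = [r["val_dice"][c] for r in reports]
            assert mean == pytest.approx(np.mean(vals))
            assert sd == pytest.approx(np.std(vals, ddof=1))

    def test_single_fold_rejected(self, rng):
        pairs = _tiny_pairs(rng)
        cfg = TrainConfig(model=UNetConfig(base_channels=2, depth=2,
                                           n_classes=2), epochs=2,
                          augment=None)
        with pytest.raises(ValueError):
            cross_validate(pairs, DatasetSplit([], [[0, 1]], seed=0), cfg)
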