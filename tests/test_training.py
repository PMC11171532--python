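"""Loss definitions, schedule, and training-loop contracts."""

import numpy as np
import pytest

from mammosub import autodiff as ad
from mammosub.model import SMALL_CONFIG, RegistrationUNet, UNetConfig, predict_displacement
from mammosub.preprocess import RegistrationPair
from mammosub.training import (
    Adam,
    TrainConfig,
    cosine_annealed_lr,
    loss_mse,
    loss_smoothness,
    total_loss,
    train,
)


def brute_force_mse(fixed, warped, mask):
    total, count = 0.0, 0
    h, w = fixed.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                total += (fixed[i, j] - warped[i, j]) ** 2
                count += 1
    return total / count


def brute_force_smoothness(field):
    _, h, w = field.shape
    row_sq, row_n, col_sq, col_n = 0.0, 0, 0.0, 0
    for k in range(2):
        for i in range(h - 1):
            for j in range(w):
                row_sq += (field[k, i + 1, j] - field[k, i, j]) ** 2
                row_n += 1
        for i in range(h):
            for j in range(w - 1):
                col_sq += (field[k, i, j + 1] - field[k, i, j]) ** 2
                col_n += 1
    return row_sq / row_n + col_sq / col_n


class TestLossOracles:
    def test_mse_matches_per_pixel_loop(self, rng):
        for _ in range(20):
            fixed = rng.random((8, 8))
            warped = rng.random((8, 8))
            mask = rng.random((8, 8)) > 0.3
            if not mask.any():
                continue
            assert loss_mse(fixed, warped, mask) == pytest.approx(
                brute_force_mse(fixed, warped, mask), abs=1e-12
            )

    def test_smoothness_matches_per_pixel_loop(self, rng):
        for _ in range(20):
            field = rng.standard_normal((2, 8, 8))
            assert loss_smoothness(field) == pytest.approx(
                brute_force_smoothness(field), abs=1e-12
            )

    def test_total_is_sum_with_lambda(self, rng):
        fixed, warped = rng.random((8, 8)), rng.random((8, 8))
        field = rng.standard_normal((2, 8, 8))
        mask = np.ones((8, 8), dtype=bool)
        m = loss_mse(fixed, warped, mask)
        s = loss_smoothness(field)
        assert total_loss(fixed, warped, field, mask, 0.0) == pytest.approx(m)
        assert total_loss(fixed, warped, field, mask, 1.0) == pytest.approx(m + s)
        # doubling lambda doubles the smoothness contribution exactly
        assert total_loss(fixed, warped, field, mask, 2.0) - m == pytest.approx(2 * s)

    def test_identical_images_zero_loss(self, rng):
        img = rng.random((8, 8))
        assert loss_mse(img, img, np.ones((8, 8), dtype=bool)) == 0.0

    def test_unit_contrast_full_mask(self):
        f, w = np.ones((4, 4)), np.zeros((4, 4))
        assert loss_mse(f, w, np.ones((4, 4), dtype=bool)) == 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            loss_mse(np.ones((4, 4)), np.ones((4, 4)), np.zeros((4, 4), dtype=bool))


class TestSmoothnessClosedForms:
    def test_zero_and_constant_fields(self):
        assert loss_smoothness(np.zeros((2, 6, 6))) == 0.0
        assert loss_smoothness(np.full((2, 6, 6), 3.7)) == 0.0

    @pytest.mark.parametrize("c", [0.5, -1.25, 2.0])
    def test_linear_field_scores_half_c_squared(self, c):
        field = np.zeros((2, 10, 12))
        field[1] = c * np.arange(12)[None, :]
        assert loss_smoothness(field) == pytest.approx(c * c / 2, rel=1e-12)

    def test_autodiff_penalty_matches_reference(self, rng):
        field = rng.standard_normal((1, 2, 8, 8)).astype(np.float32)
        ours = ad.smoothness_penalty(ad.Tensor(field)).item()
        ref = loss_smoothness(field[0].astype(np.float64))
        assert ours == pytest.approx(ref, rel=1e-5)

    def test_autodiff_mse_matches_reference(self, rng):
        fixed = rng.random((1, 1, 8, 8)).astype(np.float32)
        warped = rng.random((1, 1, 8, 8)).astype(np.float32)
        mask = (rng.random((1, 1, 8, 8)) > 0.3).astype(np.float32)
        ours = ad.masked_mse(ad.Tensor(warped), fixed, mask).item()
        ref = loss_mse(
            fixed[0, 0].astype(np.float64),
            warped[0, 0].astype(np.float64),
            mask[0, 0] > 0.5,
        )
        assert ours == pytest.approx(ref, rel=1e-5)


class TestCosineSchedule:
    def test_endpoints_and_midpoint(self):
        config = TrainConfig(epochs=800)
        assert cosine_annealed_lr(0, config) == pytest.approx(2e-4)
        assert cosine_annealed_lr(800, config) == pytest.approx(0.0, abs=1e-18)
        assert cosine_annealed_lr(400, config) == pytest.approx(1e-4)

    def test_epoch_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cosine_annealed_lr(801, TrainConfig(epochs=800))

    def test_defaults_are_study_protocol(self):
        config = TrainConfig()
        assert config.epochs == 800
        assert config.batch_size == 32
        assert config.lambda_smooth == 1.0
        assert config.base_lr == 2e-4


def _toy_pairs(rng, n, size=32):
    pairs = []
    for _ in range(n):
        img = np.zeros((size, size), dtype=np.float32)
        img[8:24, 4:20] = rng.random((16, 16)).astype(np.float32)
        mask = np.zeros((size, size), dtype=bool)
        mask[4:28, :24] = True
        pairs.append(
            RegistrationPair(fixed=img, flipped=img.copy(), mask=mask)
        )
    return pairs


class TestTrainLoop:
    def test_seeded_runs_reproduce_learning_curve(self, rng):
        pairs = _toy_pairs(rng, 4)
        config = TrainConfig(epochs=3, batch_size=2, seed=9)
        _, c1 = train(pairs, pairs[:2], config, unet_config=SMALL_CONFIG)
        _, c2 = train(pairs, pairs[:2], config, unet_config=SMALL_CONFIG)
        assert c1.train == c2.train
        assert c1.val == c2.val

    def test_validation_does_not_update_weights(self, rng):
        pairs = _toy_pairs(rng, 2)
        config = TrainConfig(epochs=1, batch_size=2, seed=0)
        model, _ = train(pairs, None, config, unet_config=SMALL_CONFIG)
        before = [p.data.copy() for p in model.parameters()]
        from mammosub.training import _batch_loss, _stack

        f, m, k = _stack(pairs)
        _batch_loss(model, f, m, k, 1.0, with_grad=False)
        for p, b in zip(model.parameters(), before):
            np.testing.assert_array_equal(p.data, b)

    def test_identity_pairs_keep_field_near_zero(self, rng):
        """Training where moving == fixed must not invent deformation."""
        pairs = _toy_pairs(rng, 8)
        config = TrainConfig(epochs=10, batch_size=4, seed=2)
        model, curve = train(pairs, pairs[:2], config, unet_config=SMALL_CONFIG)
        field = predict_displacement(model, pairs[0].fixed, pairs[0].flipped)
        assert np.abs(field)[(slice(None),) + np.nonzero(pairs[0].mask)].mean() < 0.2

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], [], TrainConfig(epochs=1, batch_size=1))
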