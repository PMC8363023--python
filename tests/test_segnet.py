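"""Network construction, augmentation, splitting and training behaviour."""
import numpy as np
import pytest

from dugongtrails import nn
from dugongtrails.evalmetrics import BufferSpec, buffered_confusion
from dugongtrails.segnet import (AugmentConfig, NetworkConfig, TrainConfig,
                                 augment_sample, build_model, predict_tile,
                                 split_dataset, train_model)

SMALL = dict(input_size_px=32, depth_levels=2, base_channels=4)


class TestBuildModel:
    def test_output_shape_and_range(self):
        model = build_model(NetworkConfig(seed=0, **SMALL))
        out = model.predict(np.random.default_rng(0).random((32, 32, 3),
                                                            dtype=np.float32))
        assert out.shape == (32, 32)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_all_zero_input_is_finite(self):
        model = build_model(NetworkConfig(seed=0, **SMALL))
        out = model.predict(np.zeros((32, 32, 3), dtype=np.float32))
        assert np.isfinite(out).all()

    def test_indivisible_input_size_names_dimension(self):
        with pytest.raises(ValueError, match="not divisible"):
            NetworkConfig(input_size_px=100, depth_levels=3)
        model = build_model(NetworkConfig(seed=0, **SMALL))
        with pytest.raises(ValueError, match="height"):
            model.predict(np.zeros((30, 32, 3), dtype=np.float32))

    def test_same_seed_builds_identical_parameters(self):
        a = build_model(NetworkConfig(seed=5, **SMALL))
        b = build_model(NetworkConfig(seed=5, **SMALL))
        assert a.param_count() == b.param_count()
        assert all(np.array_equal(pa.value, pb.value)
                   for pa, pb in zip(a.params(), b.params()))

    def test_strided_conv_downsampling_mode(self):
        model = build_model(NetworkConfig(seed=0,
                                          downsampling_mode="strided_conv_2",
                                          **SMALL))
        out = model.predict(np.random.default_rng(1).random((32, 32, 3),
                                                            dtype=np.float32))
        assert out.shape == (32, 32)

    def test_gradients_match_finite_differences(self):
        # loss gradient on a few weights; biases before batch-norm carry
        # (correctly) near-zero gradient and are skipped
        cfg = NetworkConfig(input_size_px=16, depth_levels=1, base_channels=3,
                            seed=1)
        model = build_model(cfg)
        rng = np.random.default_rng(0)
        x = rng.random((2, 16, 16, 3), dtype=np.float32)
        y = (rng.random((2, 16, 16, 1)) > 0.5).astype(np.float32)
        logits = model.forward_logits(x, train=True)
        for p in model.params():
            p.grad[...] = 0
        model.backward_from_logits(nn.bce_logits_grad(logits, y))
        checked = 0
        for p in model.params():
            flat, grad = p.value.ravel(), p.grad.ravel()
            for idx in rng.integers(0, flat.size, 2):
                if abs(grad[idx]) < 1e-4:
                    continue
                eps, old = 1e-3, flat[idx]
                flat[idx] = old + eps
                lp = nn.bce_with_logits(model.forward_logits(x, True), y)
                flat[idx] = old - eps
                lm = nn.bce_with_logits(model.forward_logits(x, True), y)
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - grad[idx]) / abs(num) < 0.05
                checked += 1
        assert checked >= 5


class TestPredictTile:
    def test_rejects_wrong_rank(self):
        model = build_model(NetworkConfig(seed=0, **SMALL))
        with pytest.raises(ValueError):
            predict_tile(model, np.zeros((32, 32)))

    def test_deterministic_for_fixed_weights(self):
        model = build_model(NetworkConfig(seed=0, **SMALL))
        tile = np.random.default_rng(3).random((32, 32, 3), dtype=np.float32)
        assert np.array_equal(predict_tile(model, tile),
                              predict_tile(model, tile))


class TestAugmentSample:
    IDENTITY = AugmentConfig(rotations_deg=(0,), flip=False,
                             gamma_range=(1.0, 1.0), contrast_range=(1.0, 1.0))

    def test_identity_draw_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16, 3), dtype=np.float32)
        mask = rng.random((16, 16)) > 0.5
        img2, mask2 = augment_sample(img, mask, self.IDENTITY, seed=0)
        assert np.allclose(img2, img)
        assert np.array_equal(mask2, mask)

    @pytest.mark.parametrize("seed", range(8))
    def test_mask_stays_binary_and_geometry_is_shared(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((16, 16, 3), dtype=np.float32)
        mask = rng.random((16, 16)) > 0.7
        img2, mask2 = augment_sample(img, mask, AugmentConfig(), seed=seed)
        assert set(np.unique(mask2)) <= {False, True}
        assert mask2.sum() == mask.sum()        # rotation/flip preserve counts
        assert img2.shape == img.shape

    def test_rotation_minus90_then_90_composes_to_identity(self):
        rot_m90 = AugmentConfig(rotations_deg=(-90,), flip=False,
                                gamma_range=(1.0, 1.0), contrast_range=(1.0, 1.0))
        rot_p90 = AugmentConfig(rotations_deg=(90,), flip=False,
                                gamma_range=(1.0, 1.0), contrast_range=(1.0, 1.0))
        rng = np.random.default_rng(1)
        img = rng.random((12, 12, 3), dtype=np.float32)
        mask = rng.random((12, 12)) > 0.5
        a, am = augment_sample(img, mask, rot_m90, seed=0)
        b, bm = augment_sample(a, am, rot_p90, seed=0)
        assert np.allclose(b, img)
        assert np.array_equal(bm, mask)

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            augment_sample(np.zeros((8, 8, 3)), np.zeros((9, 8)),
                           AugmentConfig(), 0)


class TestSplitDataset:
    def test_50_25_25_split_sizes(self):
        samples = list(range(100))
        tr, va, te = split_dataset(samples, (0.5, 0.25, 0.25), seed=0)
        assert (len(tr), len(va), len(te)) == (50, 25, 25)

    def test_everything_in_train(self):
        tr, va, te = split_dataset(list(range(17)), (1.0, 0.0, 0.0), seed=1)
        assert len(tr) == 17 and not va and not te

    def test_partition_is_disjoint_and_exhaustive(self):
        samples = list(range(53))
        tr, va, te = split_dataset(samples, (0.6, 0.2, 0.2), seed=2)
        assert sorted(tr + va + te) == samples
        assert not (set(tr) & set(va)) and not (set(tr) & set(te))
        assert not (set(va) & set(te))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([], (0.5, 0.25, 0.25), seed=0)


def _one_tile(seed=0):
    from dugongtrails.synthgen import SceneConfig, crop_tiles, render_scene

    cfg = SceneConfig(image_size_px=(64, 64), resolution_cm_per_px=1.8,
                      n_trails=2, seed=seed)
    photo, mask = render_scene(cfg)
    return crop_tiles(photo, mask, 64, 64)[0]


class TestTraining:
    def test_overfits_a_single_tile(self):
        # <= 200 gradient steps on one tile must drive the loss below 0.05
        # and the buffered tile F1 above 0.99
        tile = _one_tile()
        cfg = NetworkConfig(input_size_px=64, depth_levels=2, base_channels=8,
                            seed=0)
        tc = TrainConfig(batch_size=1, max_epochs=200, early_stop_patience=200,
                         seed=0)
        model, log = train_model(build_model(cfg), ([tile], []), tc, None)
        assert log["train_loss"].min() < 0.05
        pred = np.rint(model.predict(tile[0]) * 255) >= 125
        rep = buffered_confusion(pred, tile[1], BufferSpec(7))
        assert rep.f1 > 0.99

    def test_training_is_reproducible_and_logs_learning_rate(self):
        tiles = [_one_tile(s) for s in range(12)]
        cfg = NetworkConfig(input_size_px=64, depth_levels=2, base_channels=4,
                            seed=3)
        tc = TrainConfig(batch_size=4, max_epochs=2, early_stop_patience=5,
                         seed=3, split_fractions=(0.75, 0.25, 0.0))
        _, log1 = train_model(build_model(cfg), list(tiles), tc, AugmentConfig())
        _, log2 = train_model(build_model(cfg), list(tiles), tc, AugmentConfig())
        assert log1.equals(log2)
        assert (log1["learning_rate"] == 0.01).all()

    def test_validation_f1_improves_during_training(self, model1_training):
        _, log, _ = model1_training
        f1 = log["val_buffered_f1"]
        assert f1.max() > f1.iloc[0]
        assert f1.max() > 0.8

    def test_equivariance_under_180_rotation_smoke(self, model1_training):
        # augmentation includes 180-deg rotations, so prediction on a
        # rotated tile should roughly match the rotated prediction
        model, _, test_set = model1_training
        img, _ = test_set[0]
        p = model.predict(img)
        p_rot = model.predict(np.ascontiguousarray(np.rot90(img, 2)))
        back = np.rot90(p_rot, 2)
        assert np.mean(np.abs(p - back)) < 0.10
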