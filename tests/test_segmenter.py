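"""Segmentation network building blocks: loss, augmentation, binning,
block fusion and ensembling (training itself is exercised in the
acceptance suite)."""

import numpy as np
import pytest

from sxtmorph import segmenter as sg


class TestCombinedLoss:
    def test_perfect_prediction_is_zero(self):
        target = np.ones((3, 3, 3), int)
        probs = np.zeros((3, 3, 3, 3))
        probs[1] = 1.0
        assert sg.combined_loss(probs, target) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_probabilities_ce_floor(self):
        # background-only target: no Dice term, CE = ln L per voxel
        for n_labels in (2, 4, 5):
            probs = np.full((n_labels, 2, 2, 2), 1 / n_labels)
            target = np.zeros((2, 2, 2), int)
            assert sg.combined_loss(probs, target) == \
                pytest.approx(np.log(n_labels), rel=1e-9)

    def test_hand_computed_2x2x2(self):
        # 2 labels over 8 voxels, half foreground; independent hand
        # computation of CE and soft Dice below
        p_fg = np.array([0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.1])
        target = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        probs = np.stack([1 - p_fg, p_fg]).reshape(2, 2, 2, 2)
        ce = -np.mean(np.log(np.where(target == 1, p_fg, 1 - p_fg)))
        dice = 2 * p_fg[:4].sum() / (p_fg.sum() + 4)
        expected = ce + (1 - dice)
        assert sg.combined_loss(probs, target.reshape(2, 2, 2)) == \
            pytest.approx(expected, rel=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(3, 4, 4, 4))
        probs = sg.softmax_probs(logits)
        target = rng.integers(0, 3, (4, 4, 4))
        base = sg.combined_loss(probs, target)
        perm = rng.permutation(64)
        probs_p = probs.reshape(3, -1)[:, perm].reshape(3, 4, 4, 4)
        target_p = target.ravel()[perm].reshape(4, 4, 4)
        assert sg.combined_loss(probs_p, target_p) == \
            pytest.approx(base, rel=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            sg.combined_loss(np.ones((2, 3, 3, 3)) / 2, np.zeros((4, 4, 4),
                                                                 int))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(3, 3, 3, 3))
        target = rng.integers(0, 3, (3, 3, 3))
        loss, grad = sg._loss_and_grad_logits(logits, target)
        eps = 1e-6
        for _ in range(5):
            idx = tuple(rng.integers(0, s) for s in logits.shape)
            up = logits.copy()
            up[idx] += eps
            down = logits.copy()
            down[idx] -= eps
            numeric = (sg._loss_and_grad_logits(up, target)[0]
                       - sg._loss_and_grad_logits(down, target)[0]) / (2 * eps)
            assert grad[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)


class TestAugment:
    def test_identity_parameters(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(8, 8, 8)).astype(np.float32)
        lab = rng.integers(0, 3, (8, 8, 8))
        out_img, out_lab = sg.augment_sample(img, lab, seed=0,
                                             intensity_range=(1, 1),
                                             elastic_alpha_vox=0)
        assert np.array_equal(out_img, img)
        assert np.array_equal(out_lab, lab)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(12, 12, 12)).astype(np.float32)
        lab = rng.integers(0, 3, (12, 12, 12))
        a = sg.augment_sample(img, lab, seed=5)
        b = sg.augment_sample(img, lab, seed=5)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1], b[1])

    def test_elastic_warp_roughly_preserves_label_mass(self):
        from sxtmorph.phantoms import make_sphere_mask
        mask, _ = make_sphere_mask(0.8, 0.05)
        lab = mask.astype(np.int32)
        img = lab.astype(np.float32)
        n0 = int(lab.sum())
        any_changed = False
        for seed in range(5):
            _, warped = sg.augment_sample(img, lab, seed=seed)
            assert abs(int(warped.sum()) - n0) / n0 < 0.10
            any_changed |= not np.array_equal(warped, lab)
        assert any_changed


class TestBinning:
    def test_mean_pool_and_label_stride(self):
        img = np.arange(8, dtype=np.float32).reshape(2, 2, 2)
        assert sg.bin_volume(img, 2).shape == (1, 1, 1)
        assert sg.bin_volume(img, 2)[0, 0, 0] == pytest.approx(3.5)
        lab = np.arange(8).reshape(2, 2, 2)
        assert sg.bin_volume(lab, 2, labels=True)[0, 0, 0] == 0

    def test_unbin_restores_shape(self):
        lab = np.arange(27).reshape(3, 3, 3)
        up = sg.unbin_labels(lab, 2, (7, 6, 5))
        assert up.shape == (7, 6, 5)
        assert up[0, 0, 0] == lab[0, 0, 0]


class TestFusion:
    def test_constant_mock_exact(self):
        const = np.array([0.2, 0.3, 0.5], np.float32)

        def fn(block):
            return np.broadcast_to(const[:, None, None, None],
                                   (3,) + block.shape).copy()
        volume = np.zeros((50, 41, 37), np.float32)
        probs = sg.fuse_blocks([fn], volume, (32, 32, 32), 3)
        assert np.abs(probs - const[:, None, None, None]).max() < 1e-6

    def test_two_mock_folds_average(self):
        p = np.array([0.6, 0.4, 0.0], np.float32)
        q = np.array([0.2, 0.4, 0.4], np.float32)

        def make(c):
            return lambda b: np.broadcast_to(c[:, None, None, None],
                                             (3,) + b.shape).copy()
        volume = np.zeros((40, 40, 40), np.float32)
        probs = sg.fuse_blocks([make(p), make(q)], volume, (32, 32, 32), 3)
        expected = (p + q) / 2
        assert np.abs(probs - expected[:, None, None, None]).max() < 1e-6

    def test_weights_partition_of_unity(self):
        # fusing a field of ones must return exactly ones for any grid
        def ones(block):
            return np.ones((1,) + block.shape)
        for shape in [(32, 32, 32), (45, 33, 64), (20, 20, 20)]:
            probs = sg.fuse_blocks([ones], np.zeros(shape, np.float32),
                                   (32, 32, 32), 1)
            assert np.abs(probs - 1.0).max() < 1e-6

    def test_volume_smaller_than_block_padded(self):
        def fn(block):
            out = np.zeros((2,) + block.shape)
            out[0] = 1.0
            return out
        probs = sg.fuse_blocks([fn], np.zeros((10, 12, 8), np.float32),
                               (32, 32, 32), 2)
        assert probs.shape == (2, 10, 12, 8)
        assert np.abs(probs[0] - 1).max() < 1e-6


class TestConfig:
    def test_block_divisibility_enforced(self):
        with pytest.raises(ValueError):
            sg.SegConfig(depth=4, block_shape=(20, 20, 20))

    def test_defaults_match_full_scale_architecture(self):
        cfg = sg.SegConfig()
        assert cfg.depth == 5
        assert cfg.init_filters == 96
        assert cfg.block_shape == (96, 96, 96)
        assert cfg.bin_factor == 2
        assert cfg.n_folds == 3
        assert cfg.early_stop_patience_epochs == 50

    def test_dataset_smaller_than_folds_rejected(self):
        cfg = sg.SegConfig(depth=2, init_filters=2, block_shape=(8, 8, 8),
                           n_folds=3)
        data = [(np.zeros((8, 8, 8), np.float32),
                 np.zeros((8, 8, 8), np.int32))] * 2
        with pytest.raises(ValueError):
            sg.train_ensemble(data, cfg)


class TestEnsemble:
    def test_identical_models_equal_single(self):
        rng = np.random.default_rng(0)
        cfg = sg.SegConfig(depth=2, init_filters=2, block_shape=(8, 8, 8),
                           bin_factor=1, n_folds=1, labels=(0, 1))
        model = sg.UNet3D(cfg, rng)
        from sxtmorph.volume_io import LACVolume
        lac = LACVolume(rng.uniform(0, 1, (12, 12, 12)), 0.1)
        single = sg.TrainedEnsemble(models=[model], config=cfg,
                                    normalization=(0.0, 1.0))
        triple = sg.TrainedEnsemble(models=[model] * 3, config=cfg,
                                    normalization=(0.0, 1.0))
        p1, l1 = sg.predict(single, lac)
        p3, l3 = sg.predict(triple, lac)
        assert np.allclose(p1, p3, atol=1e-7)
        assert np.array_equal(l1.data, l3.data)

    def test_same_seed_same_first_epoch_loss(self):
        rng = np.random.default_rng(7)
        img = rng.uniform(0, 0.5, (16, 16, 16)).astype(np.float32)
        lab = (img > 0.25).astype(np.int32)
        cfg = sg.SegConfig(depth=2, init_filters=2, block_shape=(8, 8, 8),
                           bin_factor=1, n_folds=1, labels=(0, 1),
                           max_epochs=1, blocks_per_cell=1, batch_size=1,
                           seed=3)
        h1 = sg.train_ensemble([(img, lab)], cfg).histories[0]
        h2 = sg.train_ensemble([(img, lab)], cfg).histories[0]
        assert h1["train_loss"][0] == h2["train_loss"][0]


def test_checkpoint_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    cfg = sg.SegConfig(depth=2, init_filters=2, block_shape=(8, 8, 8),
                       bin_factor=1, n_folds=1, labels=(0, 1))
    model = sg.UNet3D(cfg, rng)
    ensemble = sg.TrainedEnsemble(models=[model], config=cfg,
                                  normalization=(0.1, 0.2))
    sg.save_ensemble(ensemble, tmp_path / "model")
    back = sg.load_ensemble(tmp_path / "model")
    block = rng.normal(size=(8, 8, 8)).astype(np.float32)
    assert np.allclose(back.models[0].predict_block(block),
                       model.predict_block(block), atol=1e-7)
    assert back.normalization == (0.1, 0.2)
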