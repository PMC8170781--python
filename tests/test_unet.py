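"""U-net stack: Tversky loss, augmentation, training, inference contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from woundscope.unet import (
    TverskyConfig,
    UNet,
    UNetConfig,
    UNetSegmenter,
    apply_affine,
    augment,
    one_hot,
    pad_to_multiple,
    postprocess_icd,
    softmax,
    tversky_loss,
)


def random_prob_target(seed, n=2, c=3, h=6, w=6):
    rng = np.random.default_rng(seed)
    pred = rng.random((n, c, h, w))
    pred /= pred.sum(axis=1, keepdims=True)
    target = one_hot(rng.integers(0, c, (n, h, w)), c)
    return pred, target


class TestTverskyLoss:
    def test_perfect_prediction_zero_loss(self):
        target = one_hot(np.array([[[0, 1], [2, 1]]]), 3)
        assert tversky_loss(target, target) == pytest.approx(0.0, abs=1e-6)

    def test_handcounted_toy_example(self):
        # 4 pixels, class-1 target (1,1,0,0), class-1 prediction (1,0,1,0):
        # TP=1, FP=1, FN=1 -> TI = 1/(1+0.3+0.7) = 0.5 per class
        target = one_hot(np.array([[[1, 1, 0, 0]]]), 2)
        pred = np.zeros_like(target)
        pred[0, 1, 0] = [1, 0, 1, 0]
        pred[0, 0, 0] = [0, 1, 0, 1]
        loss = tversky_loss(pred, target, TverskyConfig(alpha=0.3, beta=0.7, smooth=0.0))
        assert loss == pytest.approx(0.5, abs=1e-12)

    def test_loss_bounded_in_unit_interval(self):
        for seed in range(5):
            pred, target = random_prob_target(seed)
            assert 0.0 <= tversky_loss(pred, target) <= 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_alpha_beta_half_equals_soft_dice(self, seed):
        pred, target = random_prob_target(seed)
        tv = tversky_loss(pred, target, TverskyConfig(alpha=0.5, beta=0.5, smooth=0.0))
        # independent soft-Dice computation
        axes = (0, 2, 3)
        inter = (pred * target).sum(axis=axes)
        dice = (2 * inter) / (pred.sum(axis=axes) + target.sum(axis=axes))
        assert tv == pytest.approx(float(np.mean(1 - dice)), abs=1e-9)

    def test_shape_mismatch_rejected(self):
        pred, target = random_prob_target(0)
        with pytest.raises(ValueError):
            tversky_loss(pred[:, :, :4], target)


class TestAugment:
    def test_n_zero_empty_list(self):
        img = np.zeros((8, 8), np.float32)
        assert augment(img, img.astype(np.uint8), 0) == []

    def test_exact_quarter_rotation_is_lossless(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16)).astype(np.float32)
        lab = rng.integers(0, 3, (16, 16)).astype(np.uint8)
        aimg, alab = apply_affine(img, lab, angle_deg=90)
        assert np.array_equal(aimg, np.rot90(img))
        assert np.array_equal(alab, np.rot90(lab))

    def test_labels_stay_in_class_set(self):
        rng = np.random.default_rng(1)
        img = rng.random((32, 32)).astype(np.float32)
        lab = rng.integers(0, 3, (32, 32)).astype(np.uint8)
        for aimg, alab in augment(img, lab, 10, seed=3):
            assert set(np.unique(alab)) <= {0, 1, 2}
            assert aimg.shape == alab.shape == (32, 32)
            assert aimg.min() >= 0 and aimg.max() <= 1

    def test_geometry_applied_identically_to_image_and_label(self):
        # a label that simply marks the bright half must stay aligned
        img = np.zeros((32, 32), np.float32)
        img[:, 16:] = 1.0
        lab = (img > 0.5).astype(np.uint8)
        for aimg, alab in augment(img, lab, 5, seed=4, max_brightness=0.0):
            assert ((aimg > 0.5) == (alab == 1)).mean() > 0.98


class TestInferenceContracts:
    def test_pad_to_multiple_round_trip(self):
        rng = np.random.default_rng(0)
        for shape in [(100, 100), (97, 150), (64, 64), (1, 1)]:
            frame = rng.random(shape).astype(np.float32)
            padded, (ph, pw) = pad_to_multiple(frame, 8)
            assert padded.shape[0] % 8 == 0 and padded.shape[1] % 8 == 0
            assert np.array_equal(padded[: shape[0], : shape[1]], frame)

    def test_output_size_and_probability_sum(self):
        net = UNet(UNetConfig(n_stages=3, base_features=4, n_classes=3), seed=0)
        for shape in [(100, 100), (150, 97)]:
            probs = net.predict_proba(np.random.default_rng(1).random(shape).astype(np.float32))
            assert probs.shape == (3,) + shape
            assert np.allclose(probs.sum(axis=0), 1.0, atol=1e-5)

    def test_constant_frame_periodic_interior(self):
        # learned 2x2 upsampling makes the output periodic with period
        # 2**n_stages; on a constant input the interior prediction must be
        # exactly that periodic pattern (translation invariance modulo the
        # pooling grid), with each phase spatially constant
        net = UNet(UNetConfig(n_stages=2, base_features=4, n_classes=2), seed=0)
        probs = net.predict_proba(np.full((160, 160), 0.5, np.float32))
        interior = probs[0, 56:-56, 56:-56]
        assert np.allclose(interior[4:, :], interior[:-4, :], atol=1e-5)
        assert np.allclose(interior[:, 4:], interior[:, :-4], atol=1e-5)
        for py in range(4):
            for px in range(4):
                assert interior[py::4, px::4].std() < 1e-5

    def test_prediction_consistent_under_pre_padding(self):
        # reflect-padding the input by 8 px must not change the labels on
        # the common interior (the network is translation equivariant up to
        # pooling alignment, so compare at a pooling-aligned offset)
        net = UNet(UNetConfig(n_stages=2, base_features=4, n_classes=3), seed=3)
        rng = np.random.default_rng(5)
        frame = rng.random((64, 64)).astype(np.float32)
        base = net.predict_proba(frame).argmax(axis=0)
        padded_frame = np.pad(frame, 8, mode="reflect")
        padded = net.predict_proba(padded_frame).argmax(axis=0)
        inner = padded[8:-8, 8:-8]
        assert (inner[16:-16, 16:-16] == base[16:-16, 16:-16]).mean() > 0.95


class TestTraining:
    def tiny_data(self, n=8, size=32, seed=0):
        rng = np.random.default_rng(seed)
        imgs, labs = [], []
        for _ in range(n):
            lab = np.zeros((size, size), np.uint8)
            y, x = rng.integers(8, size - 8, 2)
            yy, xx = np.mgrid[0:size, 0:size]
            lab[(yy - y) ** 2 + (xx - x) ** 2 <= 36] = 1
            img = 0.1 + 0.7 * (lab == 1) + 0.05 * rng.random((size, size))
            imgs.append(img.astype(np.float32))
            labs.append(lab)
        return imgs, labs

    def test_loss_decreases_on_small_problem(self):
        imgs, labs = self.tiny_data()
        est = UNetSegmenter(n_classes=2, n_stages=2, base_features=4, epochs=5,
                            batch_size=4, dropout_rate=0.2, seed=0)
        est.fit(imgs, labs)
        assert est.loss_history_[-1] < est.loss_history_[0]

    def test_zero_epochs_untrained_with_empty_history(self):
        imgs, labs = self.tiny_data(n=2)
        est = UNetSegmenter(n_classes=2, n_stages=1, base_features=2, epochs=0, seed=0)
        est.fit(imgs, labs)
        assert est.loss_history_ == []
        assert est.weights_  # initialised weights exist

    def test_same_seed_same_loss_history(self):
        imgs, labs = self.tiny_data(n=4)
        kw = dict(n_classes=2, n_stages=1, base_features=2, epochs=2, batch_size=2, seed=7)
        h1 = UNetSegmenter(**kw).fit(imgs, labs).loss_history_
        h2 = UNetSegmenter(**kw).fit(imgs, labs).loss_history_
        assert h1 == h2

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            UNetSegmenter(n_stages=1, base_features=2).fit([], [])

    def test_save_load_round_trip(self, tmp_path):
        imgs, labs = self.tiny_data(n=2)
        est = UNetSegmenter(n_classes=2, n_stages=1, base_features=2, epochs=1, seed=0)
        est.fit(imgs, labs)
        est.save(tmp_path / "model.npz")
        loaded = UNetSegmenter.load(tmp_path / "model.npz")
        frame = imgs[0]
        assert np.allclose(est.predict_proba(frame), loaded.predict_proba(frame))
        assert loaded.loss_history_ == est.loss_history_


class TestPostprocessICD:
    def test_border_line_separates_two_cells(self):
        labels3 = np.ones((20, 21), np.uint8)
        labels3[:, 10] = 2  # 1-px border line
        dets, binary = postprocess_icd(labels3, min_cell_area_px2=10, median_kernel=0)
        assert len(dets) == 2
        assert not binary[:, 10].any()

    def test_small_speck_removed(self):
        labels3 = np.zeros((20, 20), np.uint8)
        labels3[5, 5:8] = 1
        dets, binary = postprocess_icd(labels3, min_cell_area_px2=50, median_kernel=0)
        assert dets == [] and not binary.any()

    def test_median_filter_removes_single_pixel_noise(self):
        rng = np.random.default_rng(0)
        clean = np.zeros((40, 40), np.uint8)
        yy, xx = np.mgrid[0:40, 0:40]
        clean[(yy - 20) ** 2 + (xx - 20) ** 2 <= 80] = 1
        noisy = clean.copy()
        flips = rng.random((40, 40)) < 0.04  # sparse salt noise
        noisy[flips & (clean == 0)] = 1
        dets_noisy, _ = postprocess_icd(noisy, min_cell_area_px2=20, median_kernel=3)
        dets_clean, _ = postprocess_icd(clean, min_cell_area_px2=20, median_kernel=3)
        assert len(dets_noisy) == len(dets_clean) == 1
        assert dets_noisy[0].centroid_x_px == pytest.approx(dets_clean[0].centroid_x_px, abs=0.5)

    def test_idsd_mode_requires_two_classes(self):
        est = UNetSegmenter(n_classes=2, n_stages=1, base_features=2, epochs=0, seed=0)
        est.fit([np.zeros((16, 16), np.float32)], [np.zeros((16, 16), np.uint8)])
        from woundscope.unet import predict_idsd

        mask = predict_idsd(np.zeros((24, 24), np.float32), est)
        assert mask.shape == (24, 24)
        with pytest.raises(ValueError):
            est.detect(np.zeros((24, 24), np.float32))
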