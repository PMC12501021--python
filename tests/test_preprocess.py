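"""Enhancement and hair-removal behaviour, checked against brute-force
window arithmetic and generator ground truth."""

import numpy as np
import pytest

from dermofusion.preprocess import (EnhancementConfig, HairRemovalConfig,
                                    LAPLACIAN_KERNELS, adaptive_average_filter,
                                    detect_hair_mask, enhance_image,
                                    estimate_noise_variance, inpaint_hair,
                                    laplacian_filter, preprocess_pipeline)

IMPULSE33 = np.array([[0, 0, 0], [0, 9, 0], [0, 0, 0]], dtype=float)


def brute_local_stats(img, w):
    """Edge-reflected per-window mean and population variance (oracle).

    numpy's "symmetric" mode matches the edge-duplicating reflection the
    implementation's filters use.
    """
    r = w // 2
    padded = np.pad(img, r, mode="symmetric")
    means = np.empty_like(img, dtype=float)
    vars_ = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            win = padded[i:i + w, j:j + w]
            means[i, j] = win.mean()
            vars_[i, j] = win.var()
    return means, vars_


class TestNoiseEstimation:
    def test_constant_image_yields_zero(self):
        assert estimate_noise_variance(np.full((9, 9), 42.0), 3) == 0.0

    def test_recovers_generating_variance(self, rng):
        img = 100.0 + rng.normal(0.0, 2.0, size=(256, 256))
        est = estimate_noise_variance(img, 7)
        assert est == pytest.approx(4.0, rel=0.15)

    def test_matches_brute_force_median(self):
        _, vars_ = brute_local_stats(IMPULSE33, 3)
        expected = float(np.median(vars_))
        assert estimate_noise_variance(IMPULSE33, 3) == pytest.approx(expected)

    def test_image_smaller_than_window_errors(self):
        with pytest.raises(ValueError):
            estimate_noise_variance(np.zeros((4, 4)), 7)


class TestAdaptiveFilter:
    def test_zero_noise_variance_is_identity(self, rng):
        img = rng.uniform(0, 255, size=(20, 23))
        np.testing.assert_allclose(adaptive_average_filter(img, 0.0, 5), img)

    def test_constant_image_unchanged(self):
        img = np.full((10, 10), 77.0)
        np.testing.assert_allclose(adaptive_average_filter(img, 50.0, 3), img)

    def test_hand_computed_center_pixel(self):
        # window mean 1, local variance 8, ratio (8-2)/8 -> 1 + 0.75*8 = 7
        out = adaptive_average_filter(IMPULSE33, 2.0, 3)
        assert out[1, 1] == pytest.approx(7.0)

    def test_output_within_local_window_bounds(self, rng):
        img = rng.uniform(0, 255, size=(16, 16))
        w = 5
        out = adaptive_average_filter(img, 30.0, w)
        r = w // 2
        padded = np.pad(img, r, mode="symmetric")
        for i in range(16):
            for j in range(16):
                win = padded[i:i + w, j:j + w]
                assert win.min() - 1e-9 <= out[i, j] <= win.max() + 1e-9

    def test_negative_noise_variance_errors(self):
        with pytest.raises(ValueError):
            adaptive_average_filter(np.zeros((5, 5)), -1.0, 3)


class TestLaplacian:
    @pytest.mark.parametrize("kernel", ["4-neighbor", "8-neighbor"])
    def test_constant_gives_zero(self, kernel):
        out = laplacian_filter(np.full((8, 8), 9.0), kernel)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    @pytest.mark.parametrize("kernel", ["4-neighbor", "8-neighbor"])
    def test_impulse_reproduces_kernel(self, kernel):
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        out = laplacian_filter(img, kernel)
        np.testing.assert_allclose(out[1:4, 1:4], LAPLACIAN_KERNELS[kernel])

    def test_linear_ramp_zero_interior(self):
        img = np.tile(np.arange(10, dtype=float) * 3.5, (8, 1))
        out = laplacian_filter(img)
        np.testing.assert_allclose(out[:, 1:-1], 0.0, atol=1e-9)

    def test_linearity(self, rng):
        x = rng.normal(size=(9, 9))
        y = rng.normal(size=(9, 9))
        lhs = laplacian_filter(2.0 * x + 3.0 * y)
        rhs = 2.0 * laplacian_filter(x) + 3.0 * laplacian_filter(y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestEnhance:
    def test_constant_image_fixed_point(self):
        img = np.full((12, 12), 99.0)
        cfg = EnhancementConfig(noise_var=0.0)
        np.testing.assert_allclose(enhance_image(img, cfg), img)

    def test_composition_of_stage_oracles(self):
        cfg = EnhancementConfig(window=3, noise_var=2.0)
        smoothed = adaptive_average_filter(IMPULSE33, 2.0, 3)
        expected = np.clip(smoothed + laplacian_filter(smoothed), 0, 255)
        np.testing.assert_allclose(enhance_image(IMPULSE33, cfg), expected)

    def test_output_clipped(self, rng):
        img = rng.uniform(0, 255, size=(24, 24, 3))
        out = enhance_image(img, EnhancementConfig())
        assert out.min() >= 0.0 and out.max() <= 255.0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            EnhancementConfig(window=4)


class TestHairMask:
    def test_hairless_image_gives_empty_mask(self):
        # large smooth mild-contrast lesion: no thin dark linear structures,
        # and a fixed threshold well above the noise floor (sigma ~ 2)
        from dermofusion.synth import LesionSpec, generate_lesion_image

        spec = LesionSpec(class_id=2, irregularity=0.02, noise_sigma=2.0,
                          size_fraction=0.4, value=0.78, saturation=0.35)
        img, _ = generate_lesion_image(spec, (128, 128), seed=5)
        cfg = HairRemovalConfig(mask_threshold=50.0)
        assert detect_hair_mask(img, cfg).sum() == 0

    def test_stroke_recall_against_truth(self, hairy_image):
        img, truth = hairy_image
        mask = detect_hair_mask(img, HairRemovalConfig()).astype(bool)
        recall = (mask & truth).sum() / truth.sum()
        assert recall >= 0.8

    def test_strictly_binary(self, hairy_image):
        img, _ = hairy_image
        assert set(np.unique(detect_hair_mask(img))) <= {0, 1}

    def test_invariant_to_additive_shift(self, hairy_image):
        img, _ = hairy_image
        scaled = np.clip(img * 0.8, 0, 203)  # keep +50 within range
        cfg = HairRemovalConfig(mask_threshold=30.0)
        np.testing.assert_array_equal(detect_hair_mask(scaled, cfg),
                                      detect_hair_mask(scaled + 50.0, cfg))

    def test_se_longer_than_image_errors(self):
        with pytest.raises(ValueError):
            detect_hair_mask(np.zeros((10, 10)), HairRemovalConfig(se_length=17))


class TestInpaint:
    def test_empty_mask_is_identity(self, rng):
        img = rng.uniform(0, 255, size=(12, 12, 3))
        out = inpaint_hair(img, np.zeros((12, 12)))
        np.testing.assert_array_equal(out, img)

    def test_constant_image_stays_constant(self):
        img = np.full((9, 9), 100.0)
        mask = np.zeros((9, 9))
        mask[3:6, 3:6] = 1
        np.testing.assert_allclose(inpaint_hair(img, mask), img)

    def test_inverse_distance_mean_on_ramp(self):
        img = np.tile(np.arange(5, dtype=float) * 10.0, (5, 1))
        mask = np.zeros((5, 5))
        mask[2, 2] = 1
        out = inpaint_hair(img, mask, HairRemovalConfig(inpaint_min_neighbors=4))
        # donors: the eight r=1 neighbours, weights 1/d
        num = den = 0.0
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == dx == 0:
                    continue
                w = 1.0 / np.hypot(dy, dx)
                num += w * img[2 + dy, 2 + dx]
                den += w
        assert out[2, 2] == pytest.approx(num / den)

    def test_never_touches_unmasked_pixels(self, rng):
        img = rng.uniform(0, 255, size=(15, 15))
        mask = rng.random((15, 15)) < 0.2
        out = inpaint_hair(img, mask)
        np.testing.assert_array_equal(out[~mask], img[~mask])

    def test_full_mask_errors(self):
        with pytest.raises(ValueError):
            inpaint_hair(np.zeros((5, 5)), np.ones((5, 5)))


class TestPipeline:
    def test_deterministic(self, hairy_image):
        img, _ = hairy_image
        out1 = preprocess_pipeline(img)
        out2 = preprocess_pipeline(img)
        np.testing.assert_array_equal(out1, out2)

    def test_untouched_outside_detected_mask(self, hairy_image):
        img, _ = hairy_image
        e_cfg, h_cfg = EnhancementConfig(), HairRemovalConfig()
        enhanced = enhance_image(img, e_cfg)
        mask = detect_hair_mask(enhanced, h_cfg).astype(bool)
        out = preprocess_pipeline(img, e_cfg, h_cfg)
        np.testing.assert_array_equal(out[~mask], enhanced[~mask])
        assert mask.sum() > 0
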