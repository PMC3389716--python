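import numpy as np
import pytest

from angioquant import (
    SegParams,
    adjust_contrast,
    lowpass_tophat,
    global_threshold,
    adaptive_threshold,
    segment,
)
from angioquant.segmentation import TIE_TOLERANCE, coerce_window


def brute_force_adaptive(img: np.ndarray, window: int) -> np.ndarray:
    """Independent per-pixel local-mean comparison with mirror padding."""
    win = coerce_window(window)
    pad = win // 2
    padded = np.pad(img, pad, mode="reflect")
    out = np.zeros(img.shape, dtype=bool)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            mean = padded[r : r + win, c : c + win].mean()
            out[r, c] = (img[r, c] - mean) > TIE_TOLERANCE
    return out


class TestAdjustContrast:
    def test_constant_image_returns_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = adjust_contrast(np.full((8, 8), 0.5))
        assert (out == 0).all()

    def test_already_saturated_image_unchanged(self):
        img = np.zeros((10, 10))
        img[:3] = 1.0
        img[5, 5] = 0.4
        out = adjust_contrast(img, 0.01)
        np.testing.assert_allclose(out, img)

    def test_linear_ramp_closed_form(self):
        img = np.linspace(0, 1, 101)[None, :].repeat(101, axis=0).T
        out = adjust_contrast(img, 0.01)
        assert (out[img <= 0.01] == 0).all()
        assert (out[img >= 0.99] == 1).all()
        interior = (img > 0.01) & (img < 0.99)
        np.testing.assert_allclose(out[interior], (img[interior] - 0.01) / 0.98, atol=1e-9)


class TestLowpassTophat:
    def test_constant_image(self):
        img = np.full((20, 20), 0.6)
        np.testing.assert_allclose(lowpass_tophat(img, 2, "opening"), img)
        np.testing.assert_allclose(lowpass_tophat(img, 2, "white-tophat"), 0.0)

    def test_opening_removes_single_bright_pixel(self):
        img = np.full((15, 15), 0.1)
        img[7, 7] = 1.0
        out = lowpass_tophat(img, 2, "opening")
        np.testing.assert_allclose(out, 0.1, atol=1e-12)

    def test_tophat_keeps_single_bright_pixel(self):
        img = np.full((15, 15), 0.1)
        img[7, 7] = 1.0
        out = lowpass_tophat(img, 2, "white-tophat")
        assert out[7, 7] == pytest.approx(0.9)

    def test_opening_preserves_large_disk(self):
        from skimage.draw import disk

        img = np.zeros((40, 40))
        rr, cc = disk((20, 20), 10)
        img[rr, cc] = 1.0
        out = lowpass_tophat(img, 2, "opening")
        # interior survives; only boundary can be nibbled
        assert out[20, 20] == 1.0
        assert out.sum() >= 0.8 * img.sum()

    def test_opening_is_anti_extensive(self):
        rng = np.random.default_rng(1)
        img = rng.random((30, 30))
        out = lowpass_tophat(img, 3, "opening")
        assert (out <= img + 1e-12).all()

    def test_radius_too_large_raises(self):
        with pytest.raises(ValueError, match="radius"):
            lowpass_tophat(np.zeros((20, 20)), 10)


class TestGlobalThreshold:
    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(2)
        img = rng.random((10, 10))
        np.testing.assert_array_equal(global_threshold(img, 0.0), img)

    def test_threshold_one_keeps_only_exact_ones(self):
        img = np.array([[0.999, 1.0], [0.5, 1.0]])
        out = global_threshold(img, 1.0)
        np.testing.assert_array_equal(out, np.array([[0.0, 1.0], [0.0, 1.0]]))

    def test_ramp_at_reference_threshold(self):
        img = np.linspace(0, 1, 100)[None, :].repeat(4, axis=0)
        out = global_threshold(img, 0.15)
        assert (out[img < 0.15] == 0).all()
        np.testing.assert_array_equal(out[img >= 0.15], img[img >= 0.15])


class TestAdaptiveThreshold:
    def test_constant_image_all_background(self):
        assert not adaptive_threshold(np.full((12, 12), 0.7), 3).any()

    def test_single_bright_pixel_window3(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        out = adaptive_threshold(img, 3)
        # center exceeds its 3x3 mean (1/9); zero neighbors do not exceed theirs
        assert out[4, 4]
        assert out.sum() == 1

    def test_bright_stripe_window10(self):
        img = np.zeros((30, 30))
        img[:, 14:17] = 1.0
        out = adaptive_threshold(img, 10)  # coerced to 11
        assert out[:, 14:17].all()
        assert not out[:, :10].any() and not out[:, 21:].any()

    @pytest.mark.parametrize("window", [3, 7, 10])
    def test_matches_brute_force_oracle(self, window):
        rng = np.random.default_rng(window)
        for _ in range(5):
            img = rng.random((24, 31))
            np.testing.assert_array_equal(
                adaptive_threshold(img, window), brute_force_adaptive(img, window)
            )

    def test_window_larger_than_image_falls_back_to_global(self):
        img = np.zeros((6, 6))
        img[2, 2] = 1.0
        with pytest.warns(UserWarning, match="global mean"):
            out = adaptive_threshold(img, 9)
        assert out[2, 2] and out.sum() == 1

    def test_even_window_coerced_odd(self):
        assert coerce_window(10) == 11
        assert coerce_window(3) == 3
        assert coerce_window(1) == 3


class TestSegment:
    def test_default_params_are_reference_optimum(self):
        p = SegParams()
        assert (p.v1_radius, p.v2_global, p.v3_window) == (15, 0.15, 10)

    def test_all_zero_image_gives_empty_mask(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = segment(np.zeros((64, 64)))
        assert not out.any()

    def test_output_shape_matches_input(self, phantom_pair):
        img, _ = phantom_pair
        assert segment(img).shape == img.shape

    def test_raising_v2_never_adds_foreground(self, easy_phantom_pair):
        """With the adaptive comparison surface frozen, a higher global
        threshold can only remove pixels from the final mask (zeroing a pixel
        never lifts it above the fixed local-mean surface)."""
        from scipy.ndimage import uniform_filter

        img, _ = easy_phantom_pair
        pre = lowpass_tophat(adjust_contrast(img), 15, "white-tophat")
        surface = uniform_filter(pre, size=coerce_window(10), mode="mirror")
        prev = None
        for v2 in (0.05, 0.15, 0.3, 0.5):
            mask = (global_threshold(pre, v2) - surface) > TIE_TOLERANCE
            if prev is not None:
                assert not (mask & ~prev).any()
            prev = mask

    def test_recovers_phantom_vessels(self, easy_phantom_pair):
        from angioquant import confusion_overlay

        img, truth = easy_phantom_pair
        counts, _ = confusion_overlay(segment(img), truth)
        assert counts.se > 0.9 and counts.sp > 0.9
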