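import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from vesselseg.io import FundusImage
from vesselseg.preprocess import (
    PipelineStageError,
    PreprocessConfig,
    adaptive_gamma,
    clahe,
    extract_green,
    median_denoise,
    minmax_normalize,
    multiscale_enhance,
    preprocess_pipeline,
)


def _img(pixels):
    return FundusImage(pixels=np.asarray(pixels, dtype=np.uint8), image_id="t")


class TestExtractGreen:
    def test_channel_selection(self):
        px = np.zeros((48, 48, 3), dtype=np.uint8)
        px[0, 0] = (10, 200, 30)
        assert extract_green(_img(px))[0, 0] == 200

    def test_all_zero(self):
        assert extract_green(_img(np.zeros((48, 48, 3)))).sum() == 0

    def test_gray_symmetry(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 256, (48, 48), dtype=np.uint8)
        px = np.stack([g, g, g], axis=-1)
        assert np.array_equal(extract_green(_img(px)), g)


class TestClahe:
    def test_constant_invariant(self):
        x = np.full((64, 64), 137.0)
        assert np.abs(clahe(x) - x).max() <= 1.0

    def test_range_contract(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 256, (64, 64)).astype(float)
        out = clahe(x)
        assert out.min() >= 0 and out.max() <= 255

    def test_checkerboard_contrast_non_decreasing(self):
        idx = np.indices((64, 64)).sum(axis=0)
        x = np.where(idx % 2 == 0, 40.0, 60.0)
        out = clahe(x)
        assert out.max() - out.min() >= x.max() - x.min()

    def test_oversized_tiles_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            clahe(np.zeros((16, 16)), tiles=(32, 32))


class TestMedian:
    def test_constant_identity(self):
        x = np.full((32, 32), 9.0)
        assert np.array_equal(median_denoise(x), x)

    def test_impulse_removed(self):
        x = np.full((21, 21), 5.0)
        x[10, 10] = 200.0
        assert median_denoise(x, 3)[10, 10] == 5.0

    def test_output_values_subset_of_input(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 50, (30, 30)).astype(float)
        out = median_denoise(x, 5)
        assert np.isin(out, np.unique(x)).all()

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            median_denoise(np.zeros((10, 10)), 4)


class TestNormalize:
    def test_direct_evaluation(self):
        out = minmax_normalize(np.array([[0.0, 128.0, 255.0]]))
        np.testing.assert_allclose(out, [[0.0, 128 / 255, 1.0]], atol=1e-12)

    @given(
        arrays(
            np.float64,
            (6, 6),
            elements=st.floats(0, 255, allow_nan=False, width=32),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_min_zero_max_one(self, x):
        if x.max() == x.min():
            return
        out = minmax_normalize(x)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_warns_and_zeros(self):
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_normalize(np.full((5, 5), 3.0))
        assert not out.any()


class TestAdaptiveGamma:
    def test_mean_half_identity(self):
        x = np.array([[0.25, 0.75], [0.0, 1.0]])
        assert x.mean() == 0.5
        np.testing.assert_allclose(adaptive_gamma(x), x, atol=1e-12)

    def test_fixed_points(self):
        x = np.array([[0.0, 1.0], [0.0, 1.0], [0.9, 0.9]])
        out = adaptive_gamma(x)
        assert out[0, 0] == 0.0 and out[0, 1] == 1.0

    def test_closed_form_quarter(self):
        x = np.full((8, 8), 0.25)
        out = adaptive_gamma(x, (0.5, 2.5))
        # gamma = log(0.5)/log(0.25) = 0.5 -> 0.25^0.5 = 0.5
        np.testing.assert_allclose(out, 0.5, atol=1e-12)

    def test_darker_images_brightened(self):
        rng = np.random.default_rng(3)
        x = np.clip(rng.random((32, 32)) * 0.4, 0, 1)
        assert adaptive_gamma(x).mean() > x.mean()

    def test_degenerate_means_warn(self):
        with pytest.warns(UserWarning):
            adaptive_gamma(np.zeros((4, 4)))
        with pytest.warns(UserWarning):
            adaptive_gamma(np.ones((4, 4)))


class TestMultiscaleEnhance:
    def test_constant_invariant(self):
        cfg = PreprocessConfig()
        x = np.full((40, 40), 0.3)
        np.testing.assert_allclose(multiscale_enhance(x, cfg), x, atol=1e-12)

    def test_k_zero_identity(self):
        cfg = PreprocessConfig(enhance_k=0.0)
        rng = np.random.default_rng(4)
        x = rng.random((40, 40))
        np.testing.assert_allclose(multiscale_enhance(x, cfg), x, atol=1e-12)

    def test_impulse_hand_evaluated(self):
        # single 0.8 pixel on 0.2 background: every white top-hat is 0.6
        # at the impulse, black top-hats 0 -> clip(0.8 + 4*0.25*0.6) = 1.0
        cfg = PreprocessConfig()
        x = np.full((31, 31), 0.2)
        x[15, 15] = 0.8
        out = multiscale_enhance(x, cfg)
        assert out[15, 15] == 1.0

    def test_linearity_in_k_before_clipping(self):
        rng = np.random.default_rng(5)
        x = rng.random((32, 32))
        c1 = PreprocessConfig(enhance_k=0.1)
        c2 = PreprocessConfig(enhance_k=0.2)
        d1 = multiscale_enhance(x, c1, clip=False) - x
        d2 = multiscale_enhance(x, c2, clip=False) - x
        np.testing.assert_allclose(d2, 2 * d1, atol=1e-10)

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(scales=(0, 1, 2, 3))


class TestPipeline:
    def test_output_in_unit_range(self, synth_sample):
        u = preprocess_pipeline(synth_sample.image)
        assert u.min() >= 0.0 and u.max() <= 1.0
        assert np.isfinite(u).all()

    def test_deterministic(self, synth_sample):
        a = preprocess_pipeline(synth_sample.image)
        b = preprocess_pipeline(synth_sample.image)
        assert np.array_equal(a, b)

    def test_contrast_not_reduced(self, synth_sample):
        s = synth_sample
        m = s.fov > 0
        v = s.vessels.vessels > 0
        g = extract_green(s.image) / 255.0
        before = g[m & ~v].mean() - g[m & v].mean()
        u = preprocess_pipeline(s.image)
        after = u[m & ~v].mean() - u[m & v].mean()
        assert after >= before

    def test_stage_error_named(self):
        rng = np.random.default_rng(6)
        img = FundusImage(
            pixels=rng.integers(0, 256, (48, 48, 3), dtype=np.uint8), image_id="t"
        )
        cfg = PreprocessConfig(clahe_tiles=(64, 64))
        with pytest.raises(PipelineStageError, match="clahe"):
            preprocess_pipeline(img, cfg)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"median_kernel": 2},
            {"scales": (1, 2, 3)},
            {"scales": (4, 3, 2, 1)},
            {"weights": (0.5, 0.5)},
            {"gamma_bounds": (2.0, 1.0)},
            {"clahe_clip": -1.0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PreprocessConfig(**kwargs)
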