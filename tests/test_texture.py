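"""GLCM engine tests against exhaustive brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segfuse.exceptions import MaskingError, QuantizationError
from segfuse.texture import (
    ANGLE_OFFSETS,
    GLCMatrix,
    compute_glcm,
    haralick_features,
    quantize_gray_levels,
    texture_feature_maps,
    window_features,
)

from oracles import brute_force_glcm, brute_force_haralick


class TestQuantize:
    def test_constant_raster_all_zero(self):
        q = quantize_gray_levels(np.full((5, 5), 3.7), levels=8)
        assert (q == 0).all()

    def test_bin_edges_half_open(self):
        # values {0, 0.5, 1} with 2 levels on (0, 1) -> {0, 1, 1}
        q = quantize_gray_levels(np.array([0.0, 0.5, 1.0]), levels=2, value_range=(0, 1))
        assert q.tolist() == [0, 1, 1]

    def test_out_of_range_clipped(self):
        q = quantize_gray_levels(np.array([-5.0, 10.0]), levels=4, value_range=(0, 1))
        assert q.tolist() == [0, 3]

    def test_invalid_range(self):
        with pytest.raises(QuantizationError):
            quantize_gray_levels(np.zeros((2, 2)), levels=4, value_range=(1.0, 1.0))

    @given(
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=30),
        st.integers(2, 16),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone(self, values, levels):
        arr = np.array(values)
        q = quantize_gray_levels(arr, levels=levels)
        order = np.argsort(arr, kind="stable")
        assert (np.diff(q[order]) >= 0).all()


class TestComputeGLCM:
    def test_two_pixel_symmetric(self):
        g = compute_glcm(np.array([[0, 1]]), ANGLE_OFFSETS[0], levels=2)
        assert g.counts[0, 1] == 1 and g.counts[1, 0] == 1
        assert g.counts.sum() == 2

    def test_constant_raster_diagonal(self):
        for offset in ANGLE_OFFSETS.values():
            g = compute_glcm(np.full((8, 8), 5), offset, levels=8)
            off_diag = g.counts.copy()
            np.fill_diagonal(off_diag, 0)
            assert off_diag.sum() == 0
            assert g.counts[5, 5] == g.counts.sum() > 0

    def test_empty_raster_zero_matrix(self):
        g = compute_glcm(np.zeros((0, 0), dtype=int), ANGLE_OFFSETS[45], levels=4)
        assert g.counts.sum() == 0

    def test_out_of_range_values_rejected(self):
        with pytest.raises(QuantizationError):
            compute_glcm(np.array([[0, 9]]), ANGLE_OFFSETS[0], levels=8)

    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_brute_force(self, symmetric):
        rng = np.random.default_rng(42)
        for _ in range(100):
            levels = int(rng.integers(2, 9))
            h, w = rng.integers(1, 7, size=2)
            q = rng.integers(0, levels, (h, w))
            for offset in ANGLE_OFFSETS.values():
                got = compute_glcm(q, offset, levels, symmetric=symmetric)
                want = brute_force_glcm(q, offset, levels, symmetric=symmetric)
                np.testing.assert_array_equal(got.counts, want)

    def test_symmetric_counts_equal_transpose(self):
        rng = np.random.default_rng(1)
        q = rng.integers(0, 8, (10, 10))
        for offset in ANGLE_OFFSETS.values():
            g = compute_glcm(q, offset, levels=8, symmetric=True)
            np.testing.assert_array_equal(g.counts, g.counts.T)

    def test_rot90_maps_angle0_to_angle90(self):
        rng = np.random.default_rng(2)
        q = rng.integers(0, 8, (9, 7))
        g0 = compute_glcm(q, ANGLE_OFFSETS[0], levels=8)
        g90 = compute_glcm(np.rot90(q), ANGLE_OFFSETS[90], levels=8)
        np.testing.assert_array_equal(g0.counts, g90.counts)


class TestHaralickFeatures:
    def test_constant_window(self):
        g = compute_glcm(np.full((8, 8), 2), ANGLE_OFFSETS[0], levels=8)
        f = haralick_features(g)
        assert (f.asm, f.contrast, f.correlation) == (1.0, 0.0, 0.0)

    def test_checkerboard(self):
        checker = np.indices((4, 4)).sum(axis=0) % 2
        f = haralick_features(compute_glcm(checker, ANGLE_OFFSETS[0], levels=2))
        assert f.asm == pytest.approx(0.5)
        assert f.contrast == pytest.approx(1.0)
        assert f.correlation == pytest.approx(-1.0)

    def test_zero_total(self):
        g = GLCMatrix(
            counts=np.zeros((4, 4), dtype=np.int64),
            levels=4,
            offset=(0, 1),
            symmetric=True,
        )
        f = haralick_features(g)
        assert (f.asm, f.contrast, f.correlation) == (0.0, 0.0, 0.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            levels = int(rng.integers(2, 9))
            q = rng.integers(0, levels, tuple(rng.integers(2, 8, size=2)))
            for offset in ANGLE_OFFSETS.values():
                g = compute_glcm(q, offset, levels)
                f = haralick_features(g)
                asm, contrast, corr = brute_force_haralick(g.counts)
                assert f.asm == pytest.approx(asm, abs=1e-12)
                assert f.contrast == pytest.approx(contrast, abs=1e-12)
                assert f.correlation == pytest.approx(corr, abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            levels = int(rng.integers(2, 9))
            q = rng.integers(0, levels, (6, 6))
            for offset in ANGLE_OFFSETS.values():
                f = haralick_features(compute_glcm(q, offset, levels))
                assert 0.0 <= f.asm <= 1.0
                assert 0.0 <= f.contrast <= (levels - 1) ** 2
                assert -1.0 <= f.correlation <= 1.0


class TestWindowFeatures:
    def test_constant_image_interior(self):
        f = window_features(np.full((16, 16), 4.2), (8, 8))
        assert (f.asm, f.contrast, f.correlation) == (1.0, 0.0, 0.0)

    def test_corner_clipped_no_error(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(16, 16))
        f = window_features(img, (0, 0), value_range=(img.min(), img.max()))
        # equals features of the explicit clipped 4x4 sub-window
        q = quantize_gray_levels(img, 8, (img.min(), img.max()))
        triples = [
            haralick_features(compute_glcm(q[:4, :4], off, 8)).as_array()
            for off in ANGLE_OFFSETS.values()
        ]
        np.testing.assert_allclose(f.as_array(), np.mean(triples, axis=0))

    def test_outside_raster_raises(self):
        with pytest.raises(IndexError):
            window_features(np.zeros((8, 8)), (8, 0))

    def test_is_mean_over_four_angles(self):
        rng = np.random.default_rng(3)
        img = rng.normal(size=(24, 24))
        vr = (img.min(), img.max())
        q = quantize_gray_levels(img, 8, vr)
        for pixel in [(12, 12), (5, 19), (20, 4)]:
            y, x = pixel
            sub = q[max(0, y - 4) : y + 4, max(0, x - 4) : x + 4]
            expect = np.mean(
                [
                    brute_force_haralick(brute_force_glcm(sub, off, 8, True))
                    for off in ANGLE_OFFSETS.values()
                ],
                axis=0,
            )
            got = window_features(img, pixel, value_range=vr).as_array()
            np.testing.assert_allclose(got, expect, atol=1e-12)


class TestTextureFeatureMaps:
    def test_empty_roi(self):
        maps = texture_feature_maps(np.zeros((16, 16)), np.zeros((16, 16), bool))
        assert maps.shape == (3, 16, 16)
        assert not maps.any()

    def test_single_pixel_roi(self):
        rng = np.random.default_rng(4)
        img = rng.normal(size=(16, 16))
        roi = np.zeros((16, 16), bool)
        roi[7, 9] = True
        maps = texture_feature_maps(img, roi)
        nz = np.nonzero(maps.any(axis=0))
        assert set(zip(*nz)) <= {(7, 9)}

    def test_shape_mismatch(self):
        with pytest.raises(MaskingError):
            texture_feature_maps(np.zeros((8, 8)), np.zeros((9, 8), bool))

    def test_matches_window_features(self, phantom_subjects):
        sub = phantom_subjects[0]
        t1ce = sub.stack.channel("T1ce")
        roi = sub.labels != 0
        maps = texture_feature_maps(t1ce, roi)
        lo, hi = t1ce[roi].min(), t1ce[roi].max()
        ys, xs = np.nonzero(roi)
        rng = np.random.default_rng(5)
        for k in rng.choice(ys.size, size=50, replace=False):
            f = window_features(t1ce, (ys[k], xs[k]), value_range=(lo, hi))
            np.testing.assert_allclose(
                maps[:, ys[k], xs[k]], f.as_array(), atol=1e-10
            )

    def test_separates_texture_regions(self):
        # two half-images with noise sd 0.02 vs 0.10 (no smoothing):
        # windowed contrast must be higher in the noisier half
        rng = np.random.default_rng(6)
        img = np.full((40, 40), 0.5)
        img[:, :20] += rng.normal(0, 0.02, (40, 20))
        img[:, 20:] += rng.normal(0, 0.10, (40, 20))
        roi = np.ones((40, 40), bool)
        maps = texture_feature_maps(img, roi)
        contrast = maps[1]
        assert contrast[8:-8, 28:36].mean() > contrast[8:-8, 4:12].mean()
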