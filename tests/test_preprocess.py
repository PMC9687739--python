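"""Artefact removal and enhancement stages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammocad import (
    EnhanceParams,
    PhantomSpec,
    apply_border_mask,
    binarize,
    clahe,
    gamma_correct,
    generate_phantom,
    largest_component_mask,
    preprocess_image,
    remove_vertical_lines,
)


class TestBorderMask:
    def test_black_image_unchanged(self):
        img = np.zeros((20, 20), dtype=np.uint8)
        assert np.array_equal(apply_border_mask(img, 5), img)

    def test_frame_zeroed_interior_intact(self):
        img = np.full((30, 30), 77, dtype=np.uint8)
        img[:3, :] = img[-3:, :] = img[:, :3] = img[:, -3:] = 255
        out = apply_border_mask(img, 5)
        expected = np.full((30, 30), 77, dtype=np.uint8)
        expected[:5, :] = expected[-5:, :] = expected[:, :5] = expected[:, -5:] = 0
        assert np.array_equal(out, expected)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (40, 50), dtype=np.uint8)
        once = apply_border_mask(img, 5)
        assert np.array_equal(apply_border_mask(once, 5), once)

    def test_thickness_too_large(self):
        with pytest.raises(ValueError):
            apply_border_mask(np.zeros((10, 10), dtype=np.uint8), 5)


class TestBinarize:
    def test_constant_zero_fixed(self):
        img = np.zeros((5, 5), dtype=np.uint8)
        assert not binarize(img, "fixed", fixed_thr=1).any()

    def test_fixed_zero_threshold_all_true(self):
        img = np.zeros((5, 5), dtype=np.uint8)
        assert binarize(img, "fixed", fixed_thr=0).all()

    def test_otsu_two_level_matches_exhaustive_search(self):
        rng = np.random.default_rng(1)
        img = np.where(rng.random((20, 20)) < 0.4, 200, 10).astype(np.uint8)
        # oracle: exhaustive threshold maximizing between-class variance
        best_t, best_v = 0, -1.0
        vals = img.ravel().astype(float)
        for t in range(1, 256):
            lo, hi = vals[vals < t], vals[vals >= t]
            if len(lo) == 0 or len(hi) == 0:
                continue
            w0, w1 = len(lo) / len(vals), len(hi) / len(vals)
            v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if v > best_v:
                best_v, best_t = v, t
        oracle_mask = img >= best_t
        assert np.array_equal(binarize(img, "otsu"), oracle_mask)
        assert np.array_equal(binarize(img, "otsu"), img == 200)

    def test_constant_image_falls_back(self):
        img = np.full((5, 5), 100, dtype=np.uint8)
        assert binarize(img, "otsu", fixed_thr=50).all()


class TestLargestComponent:
    def test_keeps_biggest_blob(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:8, 2:7] = True  # area 30
        mask[15:16, 15:20] = True  # area 5
        out = largest_component_mask(mask)
        assert out[2:8, 2:7].all()
        assert not out[15:16, 15:20].any()
        assert out.sum() == 30

    def test_single_blob_identity(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3:7, 3:7] = True
        assert np.array_equal(largest_component_mask(mask), mask)

    def test_tie_breaks_row_major(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0:2, 0:2] = True
        mask[5:7, 5:7] = True
        out = largest_component_mask(mask)
        assert out[0, 0] and not out[5, 5]

    def test_fills_interior_holes(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[2:10, 2:10] = True
        mask[5:7, 5:7] = False  # hole
        out = largest_component_mask(mask)
        assert out[5, 5]
        assert out.sum() == 64

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            largest_component_mask(np.zeros((5, 5), dtype=bool))

    def test_output_single_component_max_area(self):
        rng = np.random.default_rng(3)
        from scipy import ndimage as ndi

        mask = rng.random((30, 30)) < 0.3
        if not mask.any():
            mask[0, 0] = True
        out = largest_component_mask(mask)
        labels, n = ndi.label(out, structure=np.ones((3, 3)))
        assert n == 1
        in_labels, _ = ndi.label(mask, structure=np.ones((3, 3)))
        max_area = np.bincount(in_labels.ravel())[1:].max()
        # filling holes can only add pixels
        assert out.sum() >= max_area


class TestLineRemoval:
    def test_no_lines_unchanged(self):
        rng = np.random.default_rng(4)
        img = (20 + 5 * rng.random((60, 60))).astype(np.uint8)
        assert np.array_equal(remove_vertical_lines(img), img)

    def test_vertical_line_removed(self):
        img = np.zeros((120, 60), dtype=np.uint8)
        img[10:110, 30] = 255
        out = remove_vertical_lines(img, min_len=50)
        assert out[20:100, 30].max() == 0

    def test_horizontal_line_untouched(self):
        img = np.zeros((60, 120), dtype=np.uint8)
        img[30, 10:110] = 255
        out = remove_vertical_lines(img, angle_tol=10.0, min_len=50)
        assert np.array_equal(out, img)


class TestGamma:
    def test_identity(self):
        img = np.arange(0, 256, dtype=np.uint8).reshape(16, 16)
        assert np.array_equal(gamma_correct(img, 1.0, 1.0), img)

    def test_half_squared(self):
        img = np.full((4, 4), 128, dtype=np.uint8)  # ~0.502 normalized
        out = gamma_correct(img, 2.0, 1.0)
        assert abs(int(out[0, 0]) - round((128 / 255) ** 2 * 255)) <= 1

    def test_endpoints(self):
        img = np.array([[0, 255]], dtype=np.uint8)
        for g in (0.4, 1.0, 2.0, 3.7):
            out = gamma_correct(img, g, 1.0)
            assert out[0, 0] == 0 and out[0, 1] == 255

    @settings(max_examples=20, deadline=None)
    @given(st.floats(min_value=0.2, max_value=5.0))
    def test_monotone_and_direction(self, gamma):
        img = np.arange(0, 256, dtype=np.uint8).reshape(16, 16)
        out = gamma_correct(img, gamma, 1.0).astype(int)
        flat_in = img.ravel().astype(int)
        flat_out = out.ravel()
        order = np.argsort(flat_in)
        assert (np.diff(flat_out[order]) >= 0).all()
        if gamma < 1:
            assert (flat_out >= flat_in).all()
        if gamma > 1:
            assert (flat_out <= flat_in).all()


class TestClahe:
    def test_constant_maps_to_constant(self):
        img = np.full((64, 64), 90, dtype=np.uint8)
        out = clahe(img)
        assert out.min() == out.max()

    def test_low_contrast_ramp_gains_contrast(self):
        ramp = np.tile(np.linspace(100, 130, 64), (64, 1)).astype(np.uint8)
        out = clahe(ramp, clip_limit=8.0, tile_grid=(4, 4))
        assert out.astype(float).std() > ramp.astype(float).std()

    def test_tile_grid_too_large(self):
        with pytest.raises(ValueError):
            clahe(np.zeros((8, 8), dtype=np.uint8), tile_grid=(16, 16))


class TestFullPreprocess:
    def test_artefacts_outside_breast_zeroed(self):
        truth = generate_phantom(PhantomSpec(rng_seed=11))
        out = preprocess_image(truth.image)
        outside = truth.artefact_mask & ~truth.breast_mask
        assert out[outside].max() == 0

    def test_breast_recovered_without_artefacts(self):
        spec = PhantomSpec(border_frame=False, text_blob=False,
                           vertical_line=False, rng_seed=12)
        truth = generate_phantom(spec)
        img = truth.image
        from mammocad import binarize as bz, largest_component_mask as lcm

        recovered = lcm(bz(img))
        inter = (recovered & truth.breast_mask).sum()
        union = (recovered | truth.breast_mask).sum()
        assert inter / union >= 0.95

    def test_black_image_raises(self):
        with pytest.raises(ValueError):
            preprocess_image(np.zeros((50, 50), dtype=np.uint8))

    def test_output_shape_and_range(self, default_phantom):
        out = preprocess_image(default_phantom.image, EnhanceParams())
        assert out.shape == default_phantom.image.shape
        assert out.dtype == np.uint8
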