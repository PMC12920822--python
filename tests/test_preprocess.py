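import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.filters import threshold_otsu

from rotomics.phantoms import VolumePair
from rotomics.preprocess import (
    PairMismatchError,
    PreprocessConfig,
    check_pair,
    clean_mask,
    crop_to_bbox,
    discretize,
    modal_spacing,
    resample_isotropic,
    zscore_normalize,
)


def _pair(image, mask, spacing=(1.0, 1.0, 1.0), pid="T"):
    return VolumePair(image=np.asarray(image, dtype=float),
                      mask=np.asarray(mask, dtype=np.uint8),
                      spacing=spacing, patient_id=pid)


class TestZscore:
    def test_foreground_stats_via_independent_recount(self, rng):
        image = np.zeros((12, 12, 12))
        image[6:, :, :] = rng.normal(100.0, 5.0, size=(6, 12, 12))
        out = zscore_normalize(image)
        thresh = threshold_otsu(image, nbins=256)  # independent recomputation
        fg = image > thresh
        assert out[fg].mean() == pytest.approx(0.0, abs=1e-6)
        assert out[fg].std() == pytest.approx(1.0, abs=1e-6)

    def test_constant_foreground_raises(self):
        image = np.zeros((8, 8, 8))
        image[4:, :, :] = 100.0
        with pytest.raises(ValueError, match="constant foreground"):
            zscore_normalize(image)

    def test_affine_equivariance(self, rng):
        image = np.zeros((10, 10, 10))
        image[5:, :, :] = rng.normal(50.0, 4.0, size=(5, 10, 10))
        a = zscore_normalize(image)
        b = zscore_normalize(3.0 * image + 17.0)
        assert np.allclose(a, b, atol=1e-9)

    def test_idempotent(self, rng):
        image = np.zeros((10, 10, 10))
        image[5:, :, :] = rng.normal(50.0, 4.0, size=(5, 10, 10))
        once = zscore_normalize(image)
        twice = zscore_normalize(once)
        assert np.allclose(once, twice, atol=1e-6)


class TestCleanMask:
    def _mask_with(self, sizes):
        mask = np.zeros((20, 20, 20), dtype=np.uint8)
        start = 0
        for s in sizes:  # disjoint straight rods, separated by >1 voxel
            mask[start, 0, :s] = 1
            start += 2
        return mask

    def test_removes_below_threshold(self):
        out = clean_mask(self._mask_with([12, 4]), 10)
        assert out.sum() == 12

    def test_boundary_exactly_threshold_kept(self):
        out = clean_mask(self._mask_with([10]), 10)
        assert out.sum() == 10  # 10 is NOT fewer than 10

    def test_all_small_raises(self):
        with pytest.raises(ValueError, match="no lesion"):
            clean_mask(self._mask_with([3, 2]), 10)

    def test_never_increases_foreground(self, rng):
        mask = (rng.random((10, 10, 10)) > 0.7).astype(np.uint8)
        out = clean_mask(mask, 5)
        assert out.sum() <= mask.sum()
        from scipy import ndimage

        labels, n = ndimage.label(out, structure=np.ones((3, 3, 3)))
        if n:
            assert np.bincount(labels.ravel())[1:].min() >= 5


class TestCheckPair:
    def test_pass(self):
        mask = np.zeros((8, 8, 8), dtype=np.uint8)
        mask[4, 4, 4] = 1
        assert check_pair(_pair(np.zeros((8, 8, 8)), mask)) is not None

    def test_shape_mismatch(self):
        with pytest.raises(PairMismatchError, match="T7"):
            check_pair(_pair(np.zeros((8, 8, 8)), np.zeros((7, 8, 8)), pid="T7"))

    def test_empty_mask(self):
        with pytest.raises(PairMismatchError, match="foreground"):
            check_pair(_pair(np.zeros((8, 8, 8)), np.zeros((8, 8, 8))))


class TestCrop:
    def test_single_voxel_margin0(self):
        mask = np.zeros((9, 9, 9), dtype=np.uint8)
        mask[4, 4, 4] = 1
        out = crop_to_bbox(_pair(np.arange(729).reshape(9, 9, 9), mask), margin=0)
        assert out.image.shape == (1, 1, 1)
        assert out.image[0, 0, 0] == 4 * 81 + 4 * 9 + 4

    def test_foreground_preserved_and_bounded_growth(self):
        x, y, z = np.ogrid[-8:9, -8:9, -8:9]
        mask = ((x / 5.0) ** 2 + (y / 4.0) ** 2 + (z / 3.0) ** 2 <= 1).astype(np.uint8)
        pair = _pair(np.zeros((17, 17, 17)), mask)
        out = crop_to_bbox(pair, margin=2)
        assert out.mask.sum() == mask.sum()
        bbox_shape = tuple(int(np.ptp(np.nonzero(mask)[i])) + 1 for i in range(3))
        for got, base in zip(out.mask.shape, bbox_shape):
            assert base <= got <= base + 4

    def test_margin_clipped_to_volume(self):
        mask = np.zeros((8, 8, 8), dtype=np.uint8)
        mask[3:5, 3:5, 3:5] = 1
        out = crop_to_bbox(_pair(np.zeros((8, 8, 8)), mask), margin=100)
        assert out.image.shape == (8, 8, 8)


class TestModalSpacing:
    def _cohort(self, spacings):
        mask = np.zeros((4, 4, 4), dtype=np.uint8)
        mask[2, 2, 2] = 1
        return [_pair(np.zeros((4, 4, 4)), mask, spacing=s) for s in spacings]

    def test_mode_over_axes(self):
        # (1,1,3) x 10 patients: value 1 appears 20 times, 3 appears 10 times
        assert modal_spacing(self._cohort([(1.0, 1.0, 3.0)] * 10)) == 1.0

    def test_uniform(self):
        assert modal_spacing(self._cohort([(2.0, 2.0, 2.0)] * 3)) == 2.0

    def test_tie_breaks_small(self):
        # equal counts of 1 and 3
        assert modal_spacing(self._cohort([(1.0, 3.0, 1.0), (3.0, 1.0, 3.0)])) == 1.0


class TestResample:
    def test_identity_unchanged(self, rng):
        mask = np.zeros((8, 8, 8), dtype=np.uint8)
        mask[3:5, 3:5, 3:5] = 1
        pair = _pair(rng.random((8, 8, 8)), mask, spacing=(1.0, 1.0, 1.0))
        out = resample_isotropic(pair, 1.0)
        assert np.array_equal(out.image, pair.image)

    def test_constant_stays_constant(self):
        mask = np.ones((9, 9, 9), dtype=np.uint8)
        pair = _pair(np.full((9, 9, 9), 7.0), mask, spacing=(1.0, 1.0, 2.0))
        out = resample_isotropic(pair, 1.0)
        assert np.allclose(out.image, 7.0, atol=1e-12)

    def test_linear_ramp_downsample(self):
        # image = 3*x_mm: downsampling x2 must reproduce the ramp at new centers
        n = 17
        img = np.tile((3.0 * np.arange(n))[:, None, None], (1, n, n))
        mask = np.ones((n, n, n), dtype=np.uint8)
        out = resample_isotropic(_pair(img, mask, spacing=(1.0, 1.0, 1.0)), 2.0)
        expect = 3.0 * 2.0 * np.arange(out.image.shape[0])
        assert np.allclose(out.image[:, 2, 2], expect, atol=1e-9)

    def test_roundtrip_constant(self):
        mask = np.ones((9, 9, 9), dtype=np.uint8)
        pair = _pair(np.full((9, 9, 9), 3.0), mask, spacing=(1.0, 1.0, 1.0))
        out = resample_isotropic(resample_isotropic(pair, 2.0), 1.0)
        assert np.allclose(out.image, 3.0, atol=1e-12)

    def test_mask_vanishes_raises(self):
        mask = np.zeros((8, 8, 8), dtype=np.uint8)
        mask[1, 1, 1] = 1
        with pytest.raises(ValueError, match="vanished"):
            resample_isotropic(_pair(np.zeros((8, 8, 8)), mask), 7.5)


class TestDiscretize:
    def test_stated_rule(self):
        img = np.array([0.0, 10.0, 30.0]).reshape(3, 1, 1)
        mask = np.ones((3, 1, 1), dtype=np.uint8)
        levels = discretize(img, mask, 25.0)
        assert levels.ravel().tolist() == [1, 1, 2]

    def test_constant_single_level(self):
        img = np.full((3, 3, 3), 5.0)
        levels = discretize(img, np.ones((3, 3, 3), np.uint8), 25.0)
        assert np.all(levels == 1)

    def test_bin_edge_adjacent(self):
        img = np.array([0.0, 24.999, 25.0]).reshape(3, 1, 1)
        levels = discretize(img, np.ones((3, 1, 1), np.uint8), 25.0)
        assert levels.ravel().tolist() == [1, 1, 2]

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30),
           st.floats(0.01, 100.0))
    def test_monotone(self, values, width):
        img = np.asarray(values).reshape(-1, 1, 1)
        levels = discretize(img, np.ones(img.shape, np.uint8), width).ravel()
        order = np.argsort(values)
        assert np.all(np.diff(levels[order]) >= 0)
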