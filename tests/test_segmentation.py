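"""Normalization, thresholding, brush editing, ventricle growing, rim removal."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wmcvol.segmentation import (
    Stroke,
    ThresholdRange,
    auto_min_percent,
    normalize_intensity,
    paint,
    remove_pencil_thin_lining,
    segment_ventricles,
    threshold_segment,
)
from wmcvol.types import BinaryMask, VolumeImage


def _cube(shape=(10, 10, 10), value=0.0):
    return VolumeImage(np.full(shape, value))


def _mask(shape=(10, 10, 10), fill=False):
    return BinaryMask(np.full(shape, fill, dtype=bool))


class TestNormalize:
    def test_linear_rescale(self):
        img = _cube(value=10.0)
        img.values[0, 0, 0] = 55.0
        img.values[0, 0, 1] = 100.0
        out = normalize_intensity(img, _mask(fill=True))
        assert out.values[1, 1, 1] == pytest.approx(0.0)
        assert out.values[0, 0, 0] == pytest.approx(50.0)
        assert out.values[0, 0, 1] == pytest.approx(100.0)

    def test_identity_on_already_scaled_image(self):
        vals = np.linspace(0, 100, 1000).reshape(10, 10, 10)
        out = normalize_intensity(VolumeImage(vals), _mask(fill=True))
        assert np.allclose(out.values, vals)

    def test_outside_mask_carried_through_same_transform(self):
        img = _cube(value=-20.0)
        brain = _mask()
        brain.values[4:7, 4:7, 4:7] = True
        img.values[brain.values] = 50.0
        img.values[5, 5, 5] = 150.0
        out = normalize_intensity(img, brain)
        assert out.values[0, 0, 0] == pytest.approx((-20.0 - 50.0) / 100.0 * 100.0)

    def test_uniform_image_errors(self):
        with pytest.raises(ValueError, match="constant image"):
            normalize_intensity(_cube(value=5.0), _mask(fill=True))


class TestThreshold:
    def test_full_range_returns_search_mask(self, flat_image):
        img, brain = flat_image
        norm = normalize_intensity(img, brain)
        out = threshold_segment(norm, brain, ThresholdRange(0.0, 100.0))
        assert np.array_equal(out.values, brain.values)

    def test_degenerate_range_keeps_only_maxima(self, flat_image):
        img, brain = flat_image
        norm = normalize_intensity(img, brain)
        out = threshold_segment(norm, brain, ThresholdRange(100.0, 100.0))
        assert np.array_equal(out.values, norm.values == 100.0)

    def test_empty_search_mask_warns_and_returns_empty(self, flat_image):
        img, _ = flat_image
        with pytest.warns(UserWarning, match="empty search mask"):
            out = threshold_segment(img, _mask((12, 12, 12)), ThresholdRange(0.0))
        assert out.is_empty()

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            ThresholdRange(80.0, 60.0)
        with pytest.raises(ValueError):
            ThresholdRange(-1.0, 50.0)

    @given(st.floats(0, 100), st.floats(0, 100))
    def test_monotone_in_min_percent(self, a, b):
        """Raising the minimum threshold never adds voxels."""
        lo, hi = sorted((a, b))
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 100, size=(6, 6, 6))
        img = VolumeImage(vals)
        brain = BinaryMask(np.ones(vals.shape, dtype=bool))
        low = threshold_segment(img, brain, ThresholdRange(lo, 100.0))
        high = threshold_segment(img, brain, ThresholdRange(hi, 100.0))
        assert not (high.values & ~low.values).any()

    def test_otsu_default_separates_two_classes(self, flat_image):
        img, brain = flat_image
        norm = normalize_intensity(img, brain)
        cut = auto_min_percent(norm, brain, floor_percent=0.0)
        assert 0.0 < cut < 100.0
        seg = threshold_segment(norm, brain, ThresholdRange(cut, 100.0))
        assert np.array_equal(seg.values, norm.values == 100.0)


class TestPaint:
    def _blob_scene(self):
        """WM background 50 with a bright 3x3x3 blob (90) misclassified."""
        img = _cube((12, 12, 12), 50.0)
        img.values[4:7, 4:7, 4:7] = 90.0
        mask = _mask((12, 12, 12))
        mask.values[4:7, 4:7, 4:7] = True  # blob wrongly in the WMC mask
        mask.values[0, 0, 0] = True  # unrelated distant WMC voxel
        blob = [(i, j, k) for i in range(4, 7) for j in range(4, 7) for k in range(4, 7)]
        return img, mask, blob

    def test_remove_stroke_erases_uniform_blob_only(self):
        img, mask, blob = self._blob_scene()
        stroke = Stroke("remove", blob, spatial_radius=6.0, range_width=20.0)
        out = paint(img, mask, stroke)
        assert not out.values[4:7, 4:7, 4:7].any()
        assert out.values[0, 0, 0]  # distant voxel untouched

    def test_add_stroke_respects_range_cutoff(self):
        img, mask, blob = self._blob_scene()
        empty = _mask((12, 12, 12))
        stroke = Stroke("add", blob, spatial_radius=8.0, range_width=20.0)
        out = paint(img, empty, stroke)
        # intensity gap blob-to-background is 40 > range_width: only blob tissue added
        assert out.values[4:7, 4:7, 4:7].all()
        assert not out.values[img.values == 50.0].any()

    def test_add_then_remove_is_inverse_on_uniform_region(self):
        img, _, blob = self._blob_scene()
        start = _mask((12, 12, 12))
        start.values[0, 0, 0] = True  # pre-existing distant WMC, never affected
        stroke_add = Stroke("add", blob, spatial_radius=6.0, range_width=20.0)
        stroke_rm = Stroke("remove", blob, spatial_radius=6.0, range_width=20.0)
        out = paint(img, paint(img, start, stroke_add), stroke_rm)
        assert np.array_equal(out.values, start.values)

    def test_edits_are_spatially_local(self):
        img, mask, _ = self._blob_scene()
        img.values[:] = 70.0  # uniform: only spatial falloff limits the edit
        stroke = Stroke("remove", [(5, 5, 5)], spatial_radius=2.0, range_width=50.0)
        before = mask.values.copy()
        out = paint(img, mask, stroke)
        idx = np.indices(mask.shape)
        dist = np.sqrt(((idx - np.array([5, 5, 5])[:, None, None, None]) ** 2).sum(0))
        far = dist > 2.0
        assert np.array_equal(out.values[far], before[far])

    def test_stroke_outside_grid_rejected(self):
        img, mask, _ = self._blob_scene()
        with pytest.raises(ValueError, match="outside grid"):
            paint(img, mask, Stroke("add", [(50, 0, 0)], 2.0, 10.0))

    def test_invalid_stroke_rejected(self):
        with pytest.raises(ValueError):
            Stroke("erase", [(0, 0, 0)], 1.0, 1.0)
        with pytest.raises(ValueError):
            Stroke("add", [], 1.0, 1.0)


class TestVentricles:
    def test_zero_noise_exact_recovery(self, compact_phantom):
        spec, image, truth = compact_phantom
        norm = normalize_intensity(image, truth.brain_mask)
        out = segment_ventricles(
            norm, truth.ventricle_seeds, brain_mask=truth.brain_mask
        )
        assert np.array_equal(out.values, truth.ventricle_mask.values)

    def test_single_seed_gives_one_component_union_with_two(self, compact_phantom):
        spec, image, truth = compact_phantom
        norm = normalize_intensity(image, truth.brain_mask)
        left = segment_ventricles(norm, truth.ventricle_seeds[:1], truth.brain_mask)
        right = segment_ventricles(norm, truth.ventricle_seeds[1:], truth.brain_mask)
        both = segment_ventricles(norm, truth.ventricle_seeds, truth.brain_mask)
        assert not (left.values & right.values).any()
        assert np.array_equal(both.values, left.values | right.values)

    def test_seed_in_lesion_rejected(self, compact_phantom):
        spec, image, truth = compact_phantom
        norm = normalize_intensity(image, truth.brain_mask)
        lesion_voxel = tuple(np.argwhere(truth.dwmh_mask_true.values)[0])
        with pytest.raises(ValueError, match="non-CSF"):
            segment_ventricles(norm, [lesion_voxel], truth.brain_mask)


class TestRimRemoval:
    def test_rim_removed_caps_untouched_on_phantom(self, compact_phantom):
        """Constructed phantom: 1-voxel rim stripped entirely while the thick
        periventricular caps keep their exact voxel count."""
        spec, image, truth = compact_phantom
        wmc = truth.pvh_mask_true | truth.dwmh_mask_true | truth.rim_mask_true
        out = remove_pencil_thin_lining(wmc, truth.ventricle_mask, max_thickness=2.0)
        expected = truth.pvh_mask_true | truth.dwmh_mask_true
        assert np.array_equal(out.values, expected.values)

    def test_noop_without_ventricle_touching_wmc(self, compact_phantom):
        spec, image, truth = compact_phantom
        out = remove_pencil_thin_lining(
            truth.dwmh_mask_true, truth.ventricle_mask, max_thickness=2.0
        )
        assert np.array_equal(out.values, truth.dwmh_mask_true.values)

    def test_threshold_dominance_removes_thin_halo(self):
        """A halo thinner than max_thickness disappears entirely."""
        vent = _mask((20, 20, 20))
        vent.values[8:12, 8:12, 8:12] = True
        halo = _mask((20, 20, 20))
        halo.values[6:14, 6:14, 6:14] = True
        halo = halo - vent  # 2-voxel shell
        out = remove_pencil_thin_lining(halo, vent, max_thickness=5.0)
        assert out.is_empty()

    def test_output_subset_of_input(self, compact_phantom):
        spec, image, truth = compact_phantom
        wmc = truth.pvh_mask_true | truth.rim_mask_true
        out = remove_pencil_thin_lining(wmc, truth.ventricle_mask, max_thickness=2.0)
        assert not (out.values & ~wmc.values).any()

    def test_nonpositive_thickness_rejected(self, compact_phantom):
        spec, image, truth = compact_phantom
        with pytest.raises(ValueError, match="max_thickness"):
            remove_pencil_thin_lining(
                truth.rim_mask_true, truth.ventricle_mask, max_thickness=0.0
            )
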