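from collections import deque

import numpy as np
import pytest

from graftct.io import VoxelImage
from graftct.phantom import PhantomSpec, generate_phantom
from graftct.segmentation import (
    IntensityRange,
    SegmentationCalibration,
    default_analysis_mode,
    include_border_layer,
    masking_wand,
    propagate_seed,
    segment_four_material,
    segment_target,
)


def flood_fill_oracle(img2d: np.ndarray, seed, lo, hi) -> np.ndarray:
    """Brute-force breadth-first 4-connected flood fill."""
    mask = np.zeros(img2d.shape, dtype=bool)
    r, c = seed
    if not (lo <= img2d[r, c] <= hi):
        return mask
    queue = deque([(r, c)])
    mask[r, c] = True
    while queue:
        r, c = queue.popleft()
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < img2d.shape[0] and 0 <= cc < img2d.shape[1]:
                if not mask[rr, cc] and lo <= img2d[rr, cc] <= hi:
                    mask[rr, cc] = True
                    queue.append((rr, cc))
    return mask


def _as_image(slice2d: np.ndarray) -> VoxelImage:
    return VoxelImage(slice2d[None].astype(float), (1.0, 1.0, 1.0))


class TestMaskingWand:
    @pytest.mark.parametrize("trial", range(40))
    def test_matches_flood_fill_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        img = rng.integers(0, 6, size=(32, 32)).astype(float)
        lo = float(rng.integers(0, 3))
        hi = float(lo + rng.integers(0, 3))
        seed = (int(rng.integers(0, 32)), int(rng.integers(0, 32)))
        ours = masking_wand(_as_image(img), 0, seed, IntensityRange(lo, hi))
        oracle = flood_fill_oracle(img, seed, lo, hi)
        np.testing.assert_array_equal(ours, oracle)

    def test_uniform_slice_fills_completely(self):
        img = np.full((8, 8), 3.0)
        mask = masking_wand(_as_image(img), 0, (4, 4), IntensityRange(2, 4))
        assert mask.all()

    def test_selects_only_the_seeded_blob(self):
        img = np.zeros((10, 10))
        img[1:3, 1:3] = 5.0
        img[6:9, 6:9] = 5.0
        mask = masking_wand(_as_image(img), 0, (2, 2), IntensityRange(4, 6))
        assert mask[1:3, 1:3].all()
        assert not mask[6:9, 6:9].any()

    def test_out_of_range_seed_gives_empty_mask(self):
        img = np.zeros((5, 5))
        mask = masking_wand(_as_image(img), 0, (2, 2), IntensityRange(10, 20))
        assert not mask.any()

    def test_out_of_bounds_seed_raises(self):
        with pytest.raises(ValueError, match="seed"):
            masking_wand(_as_image(np.zeros((5, 5))), 0, (9, 0), IntensityRange(0, 1))

    @pytest.mark.parametrize("trial", range(15))
    def test_widening_the_range_never_shrinks_the_mask(self, trial):
        rng = np.random.default_rng(2000 + trial)
        img = rng.integers(0, 8, size=(24, 24)).astype(float)
        seed = (12, 12)
        narrow = IntensityRange(3, 4)
        wide = IntensityRange(2, 5)
        m_narrow = masking_wand(_as_image(img), 0, seed, narrow)
        m_wide = masking_wand(_as_image(img), 0, seed, wide)
        if m_narrow.any():
            assert (m_wide | m_narrow).sum() == m_wide.sum()  # superset


class TestBorderLayer:
    def _disk_with_gray_ring(self):
        yy, xx = np.mgrid[:21, :21]
        r = np.hypot(yy - 10, xx - 10)
        img = np.zeros((21, 21))
        img[r <= 5] = 10.0
        ring = (r > 5) & (r <= 6.5)
        img[ring] = 5.0
        return img, r <= 5, ring

    def test_zero_layers_is_identity(self):
        img, disk, _ = self._disk_with_gray_ring()
        out = include_border_layer(disk, img, IntensityRange(4, 6), layers=0)
        np.testing.assert_array_equal(out, disk)

    def test_annexes_exactly_the_adjacent_gray_ring(self):
        img, disk, ring = self._disk_with_gray_ring()
        grown = disk.copy()
        # the ring is wider than one pixel; two passes must absorb it fully
        grown = include_border_layer(grown, img, IntensityRange(4, 6), layers=3)
        np.testing.assert_array_equal(grown, disk | ring)

    def test_no_adjacent_border_pixels_means_no_change(self):
        img, disk, _ = self._disk_with_gray_ring()
        out = include_border_layer(disk, img, IntensityRange(98, 99), layers=2)
        np.testing.assert_array_equal(out, disk)

    def test_monotone_and_idempotent_when_exhausted(self):
        img, disk, ring = self._disk_with_gray_ring()
        once = include_border_layer(disk, img, IntensityRange(4, 6), layers=5)
        twice = include_border_layer(once, img, IntensityRange(4, 6), layers=5)
        assert (once | disk).sum() == once.sum()
        np.testing.assert_array_equal(once, twice)


class TestSeedPropagation:
    def test_single_pixel_mask(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[3, 1] = True
        assert propagate_seed(mask) == (3, 1)

    def test_filled_disk_returns_center(self):
        yy, xx = np.mgrid[:15, :15]
        mask = np.hypot(yy - 7, xx - 7) <= 5
        assert propagate_seed(mask) == (7, 7)

    def test_crescent_centroid_outside_lands_inside(self):
        yy, xx = np.mgrid[:31, :31]
        r = np.hypot(yy - 15, xx - 15)
        mask = (r <= 12) & (r >= 9)  # annulus: centroid is in the hole
        seed = propagate_seed(mask)
        assert mask[seed]
        # exhaustive oracle: nearest in-mask pixel to the centroid
        coords = np.argwhere(mask)
        centroid = coords.mean(axis=0)
        d2 = ((coords - centroid) ** 2).sum(axis=1)
        assert d2[np.argwhere((coords == seed).all(axis=1))[0, 0]] == d2.min()

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            propagate_seed(np.zeros((4, 4), dtype=bool))


class TestSegmentTarget:
    def test_recovers_clean_lumen_within_5_percent(self, clean_lumen_phantom):
        _, image, truth = clean_lumen_phantom
        mode = default_analysis_mode("PVA")
        target = mode.targets[0]
        z0, z1 = truth.graft_span
        seed = propagate_seed(truth.labels.mask_of("lumen")[z0])
        result = segment_target(image, target.calibration, seed, (z0, z1))
        true_count = int(truth.labels.mask_of("lumen").sum())
        assert abs(result.voxel_count - true_count) / true_count < 0.05

    def test_occluded_middle_slice_is_empty_but_traversal_continues(self):
        base = PhantomSpec(length=3.0)
        n = base.n_graft_slices
        profile = [1.0] * n
        profile[n // 2] = base.lumen_capacity  # fully occluded slice
        spec = PhantomSpec(length=3.0, custom_profile=tuple(profile))
        image, truth = generate_phantom(spec)
        mode = default_analysis_mode("PVA")
        z0, z1 = truth.graft_span
        seed = propagate_seed(truth.labels.mask_of("lumen")[z0])
        result = segment_target(image, mode.targets[0].calibration, seed, (z0, z1))
        mid = z0 + n // 2
        assert not result.masks[mid].any()
        assert result.masks[mid - 1].any() and result.masks[mid + 1].any()
        empty = [q.slice_index for q in result.qc if q.empty]
        assert mid in empty

    def test_unusable_calibration_on_first_slice_raises(self, clean_lumen_phantom):
        _, image, truth = clean_lumen_phantom
        z0, _ = truth.graft_span
        cal = SegmentationCalibration(IntensityRange(1e5, 2e5), border_layers=0)
        with pytest.raises(ValueError, match="empty"):
            segment_target(image, cal, (1, 1), (z0, image.n_slices))

    def test_wall_less_tube_fills_each_slice(self):
        data = np.full((4, 9, 9), 50.0)
        image = VoxelImage(data, (1, 1, 1))
        cal = SegmentationCalibration(IntensityRange(0, 100), border_layers=0)
        result = segment_target(image, cal, (4, 4))
        assert result.masks.all()


class TestFourMaterial:
    def test_labels_form_a_partition_of_known_materials(self, four_material_phantom):
        _, image, _ = four_material_phantom
        result = segment_four_material(image, default_analysis_mode("collagen_ePTFE"))
        assert set(np.unique(result.labels.labels)) <= {0, 1, 2, 3, 4}
        assert result.flagged_slices == []

    def test_interior_area_matches_truth_within_2_voxel_areas(self, four_material_phantom):
        _, image, truth = four_material_phantom
        result = segment_four_material(image, default_analysis_mode("collagen_ePTFE"))
        z0, z1 = truth.graft_span
        seg = result.labels.labels[z0:z1]
        tru = truth.labels.labels[z0:z1]
        seg_interior = ((seg == 1) | (seg == 2)).sum(axis=(1, 2))
        tru_interior = ((tru == 1) | (tru == 2)).sum(axis=(1, 2))
        assert np.max(np.abs(seg_interior - tru_interior)) <= 2

    def test_zero_thrombus_remainder_is_at_most_a_thin_ring(self):
        spec = PhantomSpec(
            length=3.0, contrast_mode="four_material",
            thrombus_baseline=0.0, thrombus_amplitude=0.0, rng_seed=6,
        )
        image, truth = generate_phantom(spec)
        result = segment_four_material(image, default_analysis_mode("collagen_ePTFE"))
        z0, z1 = truth.graft_span
        remainder = (result.labels.labels[z0:z1] == 2).sum(axis=(1, 2))
        ring_pixels = 2 * np.pi * (spec.inner_diameter / 2) / spec.spacing
        assert np.max(remainder) <= 1.5 * ring_pixels
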