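import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import fociquant as fq
from conftest import disk_mask
from fociquant.io import FieldImage
from oracle_utils import brute_otsu


class TestOtsu:
    def test_two_level_image_separates_classes(self):
        grid = np.array([0] * 50 + [200] * 50, dtype=np.uint8).reshape(10, 10)
        t = fq.otsu_threshold(grid)
        assert 0 <= t < 200
        assert np.array_equal(grid > t, grid == 200)

    def test_constant_image_raises(self):
        with pytest.raises(fq.DegenerateImageError):
            fq.otsu_threshold(np.full((8, 8), 7, dtype=np.uint8))

    @given(
        hnp.arrays(np.uint8, (16, 16), elements=st.integers(0, 255)).filter(
            lambda a: a.min() != a.max()
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_exhaustive_search(self, grid):
        assert fq.otsu_threshold(grid) == brute_otsu(grid)

    def test_agrees_with_skimage_partition(self, rng):
        """Independent cross-check: the induced foreground partition matches
        scikit-image's Otsu on a bimodal image."""
        from skimage.filters import threshold_otsu

        grid = np.concatenate(
            [rng.normal(50, 8, 300), rng.normal(180, 10, 200)]
        ).clip(0, 255).astype(np.uint8).reshape(25, 20)
        ours = grid > fq.otsu_threshold(grid)
        theirs = grid > threshold_otsu(grid)
        assert np.array_equal(ours, theirs)


class TestSegmentNuclei:
    def test_single_disk_detected_with_expected_area(self, rng):
        blue = np.full((200, 200), 50, dtype=np.uint16)
        mask = disk_mask((200, 200), (100, 100), 20)
        blue[mask] = 4000
        masks = fq.segment_nuclei(blue)
        assert len(masks) == 1
        assert masks[0].sum() == pytest.approx(np.pi * 20**2, rel=0.05)

    def test_border_touching_disk_excluded(self):
        blue = np.full((200, 200), 50, dtype=np.uint16)
        blue[disk_mask((200, 200), (0, 100), 20)] = 4000
        assert fq.segment_nuclei(blue, exclude_border=True) == []
        assert len(fq.segment_nuclei(blue, exclude_border=False)) == 1

    def test_constructed_scene_six_disks_three_survive(self):
        """6 disks: 2 touch the border, 1 is below min_area -> 3 masks."""
        blue = np.full((300, 300), 50, dtype=np.uint16)
        centers_r = [(60, 60, 15), (150, 150, 15), (230, 80, 15)]  # survivors
        centers_r += [(5, 200, 15), (280, 280, 25)]  # border-touching
        centers_r += [(100, 250, 4)]  # too small
        for r, c, rad in centers_r:
            blue[disk_mask((300, 300), (r, c), rad)] = 4000
        masks = fq.segment_nuclei(blue, min_area_px=200)
        assert len(masks) == 3

    def test_min_area_monotonicity(self, rng):
        blue = np.full((300, 300), 40, dtype=np.uint16)
        for r, c, rad in [(50, 50, 8), (120, 200, 12), (220, 90, 18), (250, 250, 6)]:
            blue[disk_mask((300, 300), (r, c), rad)] = 3000
        counts = [
            len(fq.segment_nuclei(blue, min_area_px=a, opening_radius=1))
            for a in (50, 150, 400, 900)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_masks_pairwise_disjoint_and_raster_ordered(self, small_scene):
        field, truth, processed, _ = small_scene
        union = np.zeros(field.shape, dtype=int)
        for proc in processed:
            union += proc.record.mask
        assert union.max() <= 1


class TestTraceOutline:
    def test_square_perimeter(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True  # 10x10 solid square
        outline = fq.trace_outline(mask)
        assert len(outline) == 36
        rs = [r for r, _ in outline]
        cs = [c for _, c in outline]
        assert min(rs) == 2 and max(rs) == 11 and min(cs) == 2 and max(cs) == 11

    def test_disk_outline_close_to_circumference(self):
        mask = disk_mask((40, 40), (20, 20), 15)
        outline = fq.trace_outline(mask)
        assert len(outline) == pytest.approx(2 * np.pi * 15, rel=0.15)

    def test_single_pixel_mask(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 3] = True
        assert fq.trace_outline(mask) == {(2, 3)}

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            fq.trace_outline(np.zeros((5, 5), dtype=bool))

    def test_outline_pixels_have_outside_4_neighbor(self):
        mask = disk_mask((30, 30), (14, 16), 9)
        padded = np.pad(mask, 1)
        for r, c in fq.trace_outline(mask):
            nbrs = [padded[r, c + 1], padded[r + 2, c + 1], padded[r + 1, c], padded[r + 1, c + 2]]
            assert mask[r, c] and not all(nbrs)

    def test_canny_method_on_disk(self):
        mask = disk_mask((50, 50), (25, 25), 15)
        outline = fq.trace_outline(mask, method="canny")
        assert outline  # nonempty, one-pixel-ish band near the rim
        for r, c in outline:
            d = np.hypot(r - 25, c - 25)
            assert 12 <= d <= 16


def _two_nuclei_field():
    """Two diagonal nuclei whose bounding rectangles overlap."""
    shape = (60, 60)
    m1 = disk_mask(shape, (25, 25), 12)
    m2 = disk_mask(shape, (38, 40), 12) & ~m1
    rng = np.random.default_rng(3)
    chans = {
        role: rng.integers(1, 5000, size=shape).astype(np.uint16)
        for role in ("blue", "green", "red")
    }
    return FieldImage(**chans), m1, m2


class TestCropNucleus:
    def test_isolated_nucleus_identity_and_conservation(self):
        field, m1, _ = _two_nuclei_field()
        rec = fq.crop_nucleus(field, m1)
        r0, r1, c0, c1 = rec.bbox
        local = m1[r0:r1, c0:c1]
        np.testing.assert_array_equal(rec.sub_green[local], field.green[r0:r1, c0:c1][local])
        assert rec.sub_green[~local].sum() == 0
        assert int(rec.sub_green.sum()) == int(field.green[m1].sum(dtype=np.int64))

    def test_overlapping_bboxes_exclude_each_other(self):
        field, m1, m2 = _two_nuclei_field()
        rec1 = fq.crop_nucleus(field, m1)
        rec2 = fq.crop_nucleus(field, m2)
        for rec, other in ((rec1, m2), (rec2, m1)):
            r0, r1, c0, c1 = rec.bbox
            other_local = other[r0:r1, c0:c1]
            assert rec.sub_red[other_local].sum() == 0

    def test_total_intensity_partition_over_mask_union(self):
        field, m1, m2 = _two_nuclei_field()
        total = sum(
            int(fq.crop_nucleus(field, m).sub_green.sum(dtype=np.int64)) for m in (m1, m2)
        )
        # brute-force pixel loop over the union
        expected = sum(
            int(field.green[r, c])
            for r in range(60)
            for c in range(60)
            if m1[r, c] or m2[r, c]
        )
        assert total == expected

    def test_bbox_is_minimal(self):
        field, m1, _ = _two_nuclei_field()
        rec = fq.crop_nucleus(field, m1)
        r0, r1, c0, c1 = rec.bbox
        rows, cols = np.nonzero(m1)
        assert (r0, r1, c0, c1) == (rows.min(), rows.max() + 1, cols.min(), cols.max() + 1)

    def test_out_of_shape_mask_rejected(self):
        field, _, _ = _two_nuclei_field()
        with pytest.raises(fq.DimensionError):
            fq.crop_nucleus(field, np.ones((10, 10), dtype=bool))
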