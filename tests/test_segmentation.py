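"""Thresholding, connected components, the solidity/area filter, and area."""

import numpy as np
import pytest

from tumnet import (
    BinaryMask,
    ComponentStats,
    GrayImage,
    ShapeMismatchError,
    binarize,
    dice,
    extract_components,
    filter_tumor,
    segment,
    tumor_area_mm2,
    tumor_outline,
)


class TestBinarize:
    def test_all_zero_image_fixed_threshold_gives_empty_mask(self):
        mask, t = binarize(GrayImage(np.zeros((6, 6))), "fixed", threshold=10)
        assert mask.count == 0 and t == 10

    def test_binary_image_fixed_threshold_128(self):
        arr = np.zeros((4, 4))
        arr[1:3, 1:3] = 255
        mask, _ = binarize(GrayImage(arr), "fixed", threshold=128)
        assert np.array_equal(mask.pixels, arr == 255)

    def test_otsu_threshold_falls_between_bimodal_modes(self, rng):
        # two well-separated Gaussian intensity modes
        arr = np.concatenate(
            [rng.normal(60, 8, 600), rng.normal(190, 8, 400)]
        ).clip(0, 255).reshape(25, 40)
        img = GrayImage(arr)
        mask, t = binarize(img, "otsu")
        # any cut in the (empty) gap between the modes maximizes the
        # between-class variance; the threshold must land there
        assert 80 < t < 170
        # the chosen cut must achieve the maximal between-class variance
        # found by exhaustive search (ties across the empty gap allowed)
        vals = np.rint(arr).ravel()
        def between_class_var(t):
            fg, bg = vals[vals > t], vals[vals <= t]
            if len(fg) == 0 or len(bg) == 0:
                return 0.0
            w1, w2 = len(bg) / len(vals), len(fg) / len(vals)
            return w1 * w2 * (bg.mean() - fg.mean()) ** 2
        best = max(between_class_var(t) for t in range(256))
        assert between_class_var(int(t)) >= 0.999 * best

    def test_constant_image_otsu_gives_empty_mask(self):
        mask, _ = binarize(GrayImage(np.full((5, 5), 7.0)), "otsu")
        assert mask.count == 0

    def test_fixed_without_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(GrayImage(np.zeros((3, 3))), "fixed")


class TestComponents:
    def test_empty_mask_gives_no_components(self):
        assert extract_components(BinaryMask(np.zeros((5, 5), bool))) == []

    def test_filled_square(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        (comp,) = extract_components(BinaryMask(mask))
        assert comp.area_px == 100
        assert comp.solidity == 1.0
        assert comp.centroid == (9.5, 9.5)

    def test_filled_disk_is_highly_solid(self):
        rr, cc = np.mgrid[0:30, 0:30]
        mask = (rr - 15) ** 2 + (cc - 15) ** 2 <= 8**2
        (comp,) = extract_components(BinaryMask(mask))
        assert comp.solidity >= 0.9

    def test_diagonal_touching_pixels_are_one_component(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = mask[1, 1] = True  # 8-connectivity joins diagonals
        assert len(extract_components(BinaryMask(mask))) == 1


class TestFilter:
    def comp(self, area, solidity):
        return ComponentStats(1, area, solidity, (0.0, 0.0), (0, 0, 1, 1))

    @pytest.mark.parametrize(
        "area, solidity, kept",
        [
            (150, 0.9, True),
            (50, 0.95, False),   # too small
            (150, 0.5, False),   # too stringy
            (100, 0.7, False),   # exact boundary fails the strict rule
            (101, 0.71, True),
        ],
    )
    def test_solidity_and_area_rule(self, area, solidity, kept):
        k, r = filter_tumor([self.comp(area, solidity)])
        assert (len(k) == 1) == kept
        assert len(k) + len(r) == 1

    def test_partition_preserves_all_components(self, rng):
        comps = [
            self.comp(int(a), float(s))
            for a, s in zip(rng.integers(1, 300, 20), rng.uniform(0.1, 1.0, 20))
        ]
        kept, rejected = filter_tumor(comps)
        assert sorted(map(id, kept + rejected)) == sorted(map(id, comps))

    def test_nonpositive_thresholds_rejected(self):
        with pytest.raises(ValueError):
            filter_tumor([], min_solidity=0)


class TestArea:
    @pytest.mark.parametrize("px, mm2", [(100, 26.4), (0, 0.0), (15, 3.96)])
    def test_area_formula(self, px, mm2):
        assert tumor_area_mm2(px) == pytest.approx(mm2)

    def test_linearity(self):
        assert tumor_area_mm2(70) + tumor_area_mm2(30) == pytest.approx(tumor_area_mm2(100))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            tumor_area_mm2(-1)


class TestOutline:
    def test_empty_mask_returns_image_unmarked(self, rng):
        img = GrayImage(rng.integers(0, 200, (10, 10)).astype(float))
        out = tumor_outline(BinaryMask(np.zeros((10, 10), bool)), img)
        assert np.array_equal(out.pixels, img.pixels)

    def test_square_mask_outline_is_perimeter(self):
        mask = np.zeros((12, 12), bool)
        mask[3:9, 3:9] = True
        img = GrayImage(np.zeros((12, 12)))
        out = tumor_outline(BinaryMask(mask), img)
        marked = out.pixels == 255
        interior = np.zeros_like(mask)
        interior[4:8, 4:8] = True
        assert np.array_equal(marked, mask & ~interior)

    def test_disk_outline_is_closed_one_pixel_boundary(self):
        rr, cc = np.mgrid[0:30, 0:30]
        mask = (rr - 15) ** 2 + (cc - 15) ** 2 <= 10**2
        img = GrayImage(np.zeros((30, 30)))
        out = tumor_outline(BinaryMask(mask), img)
        marked = out.pixels == 255
        # boundary only where mask is set, and every mask-edge pixel marked
        assert marked.sum() > 0
        assert np.all(mask[marked])
        from scipy.ndimage import binary_erosion
        assert np.array_equal(marked, mask & ~binary_erosion(mask, np.ones((3, 3))))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeMismatchError):
            tumor_outline(BinaryMask(np.zeros((5, 5), bool)), GrayImage(np.zeros((6, 6))))


class TestSegmentEndToEnd:
    def test_segment_totals_are_consistent(self, rng):
        arr = np.full((60, 60), 20.0)
        arr[10:30, 10:30] = 220.0  # 400-px bright square
        result = segment(GrayImage(arr))
        assert result.total_tumor_px == sum(c.area_px for c in result.components_kept)
        assert result.tumor_area_mm2 == pytest.approx(result.total_tumor_px * 0.264)
        assert result.total_tumor_px == 400

    def test_dice_identities(self):
        m = np.zeros((5, 5), bool)
        m[1:3, 1:3] = True
        assert dice(m, m) == 1.0
        assert dice(m, np.zeros((5, 5), bool)) == 0.0
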