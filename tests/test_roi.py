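import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glottiseg.roi import (
    PixelBox,
    build_roi_context,
    combine_bboxes,
    crop_resize,
    largest_2to1_in_image,
    legacy_resize,
    mask_bbox,
    sample_roi,
    smallest_enclosing_2to1,
)


def brute_force_smallest_2to1(b_ref: PixelBox) -> int:
    """Minimal width w such that some h=2w box contains b_ref (position-free)."""
    w = 1
    while not (w >= b_ref.w and 2 * w >= b_ref.h):
        w += 1
    return w


def brute_force_largest_2to1(b_ref: PixelBox, H: int, W: int) -> int:
    """Maximal width over all integer 2:1 boxes inside the image containing b_ref."""
    best = 0
    for w in range(1, min(W, H // 2) + 1):
        h = 2 * w
        for r0 in range(0, H - h + 1):
            for c0 in range(0, W - w + 1):
                if PixelBox(r0, c0, h, w).contains(b_ref):
                    best = max(best, w)
    return best


class TestMaskBbox:
    def test_single_pixel(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        m[3, 5] = 1
        assert mask_bbox(m) == PixelBox(3, 5, 1, 1)

    def test_empty_mask_is_none(self):
        assert mask_bbox(np.zeros((4, 4), dtype=np.uint8)) is None

    def test_two_corners(self):
        m = np.zeros((8, 12), dtype=np.uint8)
        m[0, 0] = m[4, 9] = 1
        assert mask_bbox(m) == PixelBox(0, 0, 5, 10)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            mask_bbox(np.full((4, 4), 2))


class TestCombine:
    def test_identity_and_commutativity(self):
        a, b = PixelBox(0, 0, 2, 2), PixelBox(8, 8, 2, 2)
        assert combine_bboxes([a]) == a
        assert combine_bboxes([a, b]) == PixelBox(0, 0, 10, 10)
        assert combine_bboxes([b, a]) == combine_bboxes([a, b])

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            combine_bboxes([])


class TestSmallest2to1:
    @pytest.mark.parametrize(
        "ref,expect_hw",
        [
            (PixelBox(0, 0, 30, 10), (30, 15)),
            (PixelBox(0, 0, 20, 20), (40, 20)),
            (PixelBox(5, 5, 20, 10), (20, 10)),  # already 2:1 -> itself
        ],
    )
    def test_examples(self, ref, expect_hw):
        out = smallest_enclosing_2to1(ref)
        assert (out.h, out.w) == expect_hw
        assert out.contains(ref)

    @given(
        r0=st.integers(0, 20), c0=st.integers(0, 20),
        h=st.integers(1, 30), w=st.integers(1, 30),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_bruteforce_minimal_width(self, r0, c0, h, w):
        ref = PixelBox(r0, c0, h, w)
        out = smallest_enclosing_2to1(ref)
        assert out.h == 2 * out.w
        assert out.contains(ref)
        assert out.w == brute_force_smallest_2to1(ref)


class TestLargest2to1:
    def test_tiny_central_ref_in_square_image(self):
        out = largest_2to1_in_image(PixelBox(48, 48, 4, 4), 100, 100)
        assert (out.h, out.w) == (100, 50)
        assert out.within_image(100, 100)

    def test_2to1_image_gives_full_image(self):
        out = largest_2to1_in_image(PixelBox(100, 100, 10, 10), 512, 256)
        assert out == PixelBox(0, 0, 512, 256)

    def test_nests_smallest(self):
        ref = PixelBox(10, 10, 12, 5)
        ctx = build_roi_context([], 64, 48)  # empty-video fallback context
        assert ctx.b_max.contains(ctx.b_min) or ctx.b_max.area >= ctx.b_min.area
        small = smallest_enclosing_2to1(ref)
        big = largest_2to1_in_image(ref, 64, 48)
        assert big.area >= small.area


def test_geometry_matches_exhaustive_search_on_random_masks(rng):
    """Both 2:1 box constructions agree with exhaustive search over all
    integer 2:1 boxes on small random masks."""
    for _ in range(40):
        H = int(rng.integers(20, 64))
        W = int(rng.integers(10, 64))
        mask = np.zeros((H, W), dtype=np.uint8)
        n_pix = int(rng.integers(1, 12))
        rr = rng.integers(0, H, n_pix)
        cc = rng.integers(0, W, n_pix)
        mask[rr, cc] = 1
        ref = mask_bbox(mask)
        small = smallest_enclosing_2to1(ref)
        assert small.w == brute_force_smallest_2to1(ref)
        if small.h <= H and small.w <= W:
            big = largest_2to1_in_image(ref, H, W)
            assert big.within_image(H, W) and big.contains(ref)
            assert big.w == brute_force_largest_2to1(ref, H, W)


class TestSampleRoi:
    def _ctx(self):
        mask = np.zeros((64, 48), dtype=np.uint8)
        mask[20:36, 20:28] = 1
        return build_roi_context([mask], 64, 48)

    def test_degenerate_feasible_set_returns_unique_box(self):
        mask = np.zeros((64, 32), dtype=np.uint8)
        mask[0:64, 0:32] = 1  # b_ref = whole image, already 2:1
        ctx = build_roi_context([mask], 64, 32)
        assert ctx.b_min == ctx.b_max
        assert sample_roi(ctx, 0) == ctx.b_min

    def test_all_draws_contain_ref_and_stay_in_image(self):
        ctx = self._ctx()
        rng = np.random.default_rng(0)
        for _ in range(500):
            box = sample_roi(ctx, rng)
            assert box.h == 2 * box.w
            assert box.contains(ctx.b_ref)
            assert box.within_image(ctx.image_h, ctx.image_w)

    def test_width_distribution_uniform(self):
        ctx = self._ctx()
        rng = np.random.default_rng(1)
        widths = [sample_roi(ctx, rng).w for _ in range(10_000)]
        lo, hi = ctx.b_min.w, ctx.b_max.w
        counts = np.bincount(widths, minlength=hi + 1)[lo : hi + 1]
        from scipy.stats import chisquare

        stat, p = chisquare(counts)
        assert p > 0.01

    def test_epoch_reseeding_changes_roi(self):
        ctx = self._ctx()
        boxes = {sample_roi(ctx, seed) for seed in range(20)}
        assert len(boxes) > 1


class TestCropResize:
    def test_full_image_identity(self, rng):
        img = rng.integers(0, 255, (32, 16)).astype(np.uint8)
        mask = (rng.random((32, 16)) > 0.7).astype(np.uint8)
        out_i, out_m = crop_resize(img, mask, PixelBox(0, 0, 32, 16), 32, 16)
        assert (out_i == img).all() and (out_m == mask).all()

    def test_output_mask_binary_and_shape(self, rng):
        img = rng.integers(0, 255, (40, 30)).astype(np.uint8)
        mask = (rng.random((40, 30)) > 0.5).astype(np.uint8)
        out_i, out_m = crop_resize(img, mask, PixelBox(4, 3, 32, 16), 64, 32)
        assert out_i.shape == (64, 32) and out_m.shape == (64, 32)
        assert set(np.unique(out_m)) <= {0, 1}

    def test_nearest_downscale_of_solid_rectangle(self):
        mask = np.zeros((64, 32), dtype=np.uint8)
        mask[16:48, 8:24] = 1
        img = (mask * 200).astype(np.uint8)
        _, out_m = crop_resize(img, mask, PixelBox(0, 0, 64, 32), 32, 16)
        expect = np.zeros((32, 16), dtype=np.uint8)
        expect[8:24, 4:12] = 1
        assert (out_m == expect).all()

    def test_non_2to1_target_warns(self, rng):
        img = rng.integers(0, 255, (16, 16)).astype(np.uint8)
        with pytest.warns(UserWarning):
            crop_resize(img, None, PixelBox(0, 0, 16, 16), 16, 16)


class TestLegacyResize:
    def test_identity_at_native_2to1(self, rng):
        img = rng.integers(0, 255, (64, 32)).astype(np.uint8)
        out, _ = legacy_resize(img, None, 64, 32)
        assert (out == img).all()

    def test_square_input_distorts_anisotropically(self):
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[16:48, 16:48] = 1  # square blob
        img = (mask * 200).astype(np.uint8)
        _, out_m = legacy_resize(img, mask, 64, 32)
        box = mask_bbox(out_m)
        # vertical extent preserved, horizontal halved: 2:1 distortion
        assert abs(box.h - 32) <= 1 and abs(box.w - 16) <= 1

    def test_mask_area_scales_with_product_of_factors(self):
        mask = np.zeros((40, 60), dtype=np.uint8)
        mask[10:30, 12:48] = 1
        img = (mask * 120).astype(np.uint8)
        _, out_m = legacy_resize(img, mask, 80, 30)
        # factors 2.0 and 0.5 -> area unchanged within discretization
        assert abs(int(out_m.sum()) - int(mask.sum())) / mask.sum() < 0.1
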