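"""Region-of-interest preprocessing with a fixed 2:1 (height:width) aspect.

Endoscopic glottis images come from cameras with wildly different
resolutions.  Naively resizing every frame to a fixed network input
distorts the glottis geometry.  The ROI method instead builds, per video,
a reference box ``B_ref`` around all annotated glottis masks, the smallest
2:1 box containing it (``b_min``) and the largest 2:1 box that fits in the
image (``b_max``), then crops a randomly placed 2:1 box between the two
before resizing — the aspect ratio is preserved end to end, so the glottis
is never stretched.

Boxes use half-open pixel intervals ``[r0, r0+h) x [c0, c0+w)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = [
    "PixelBox",
    "RoiContext",
    "mask_bbox",
    "combine_bboxes",
    "smallest_enclosing_2to1",
    "largest_2to1_in_image",
    "build_roi_context",
    "sample_roi",
    "crop_resize",
    "legacy_resize",
    "pad_to_fit_2to1",
]


@dataclass(frozen=True)
class PixelBox:
    """Axis-aligned integer rectangle: top-left (r0, c0), extents (h, w)."""

    r0: int
    c0: int
    h: int
    w: int

    def __post_init__(self) -> None:
        if self.h < 1 or self.w < 1:
            raise ValueError(f"box extents must be >= 1, got h={self.h}, w={self.w}")

    @property
    def r1(self) -> int:
        return self.r0 + self.h

    @property
    def c1(self) -> int:
        return self.c0 + self.w

    @property
    def area(self) -> int:
        return self.h * self.w

    def contains(self, other: "PixelBox") -> bool:
        return (
            self.r0 <= other.r0
            and self.c0 <= other.c0
            and self.r1 >= other.r1
            and self.c1 >= other.c1
        )

    def within_image(self, image_h: int, image_w: int) -> bool:
        return self.r0 >= 0 and self.c0 >= 0 and self.r1 <= image_h and self.c1 <= image_w


@dataclass(frozen=True)
class RoiContext:
    """Per-video ROI sampling bounds: b_min ⊆ B_Var ⊆ b_max, all ⊇ b_ref."""

    b_ref: PixelBox
    b_min: PixelBox
    b_max: PixelBox
    image_h: int
    image_w: int


def _check_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be strictly binary (values in {0, 1})")
    return mask


def mask_bbox(mask: np.ndarray) -> PixelBox | None:
    """Tightest box over the mask foreground; None for an empty mask."""
    mask = _check_binary(mask)
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        return None
    cols = np.flatnonzero(mask.any(axis=0))
    return PixelBox(
        r0=int(rows[0]),
        c0=int(cols[0]),
        h=int(rows[-1] - rows[0] + 1),
        w=int(cols[-1] - cols[0] + 1),
    )


def combine_bboxes(boxes: list[PixelBox]) -> PixelBox:
    """Minimal box enclosing every input box (the per-video reference box)."""
    boxes = [b for b in boxes if b is not None]
    if not boxes:
        raise ValueError("no reference box: every mask in the video is empty")
    r0 = min(b.r0 for b in boxes)
    c0 = min(b.c0 for b in boxes)
    r1 = max(b.r1 for b in boxes)
    c1 = max(b.c1 for b in boxes)
    return PixelBox(r0=r0, c0=c0, h=r1 - r0, w=c1 - c0)


def _place_containing(size: int, ref_start: int, ref_extent: int, limit: int | None) -> int:
    """Start index for a box of `size` containing [ref_start, ref_start+ref_extent),
    centered when possible; ties resolve toward smaller indices."""
    center2 = 2 * ref_start + ref_extent  # twice the reference center
    start = (center2 - size) // 2
    lo = ref_start + ref_extent - size
    hi = ref_start
    if limit is not None:
        lo = max(lo, 0)
        hi = min(hi, limit - size)
    return int(min(max(start, lo), hi))


def smallest_enclosing_2to1(b_ref: PixelBox) -> PixelBox:
    """Smallest h = 2w box containing b_ref, centered on it.

    May extend past the image border for reference boxes near an edge; use
    :func:`pad_to_fit_2to1` or the clipping in :func:`build_roi_context` to
    keep crops in-image.
    """
    w = max(b_ref.w, -(-b_ref.h // 2))  # ceil(h/2)
    h = 2 * w
    r0 = _place_containing(h, b_ref.r0, b_ref.h, None)
    c0 = _place_containing(w, b_ref.c0, b_ref.w, None)
    return PixelBox(r0=r0, c0=c0, h=h, w=w)


def largest_2to1_in_image(b_ref: PixelBox, image_h: int, image_w: int) -> PixelBox:
    """Maximal-area h = 2w box inside the image that contains b_ref."""
    w = min(image_w, image_h // 2)
    w_min = max(b_ref.w, -(-b_ref.h // 2))
    if w < w_min:
        # smallest 2:1 box does not fit; callers pad first (pad_to_fit_2to1)
        w = w_min
    h = 2 * w
    r0 = _place_containing(h, b_ref.r0, b_ref.h, image_h if h <= image_h else None)
    c0 = _place_containing(w, b_ref.c0, b_ref.w, image_w if w <= image_w else None)
    return PixelBox(r0=r0, c0=c0, h=h, w=w)


def pad_to_fit_2to1(
    image: np.ndarray, mask: np.ndarray | None, b_ref: PixelBox
) -> tuple[np.ndarray, np.ndarray | None, PixelBox]:
    """Edge-replicate pad so the smallest 2:1 box around b_ref fits in-image.

    The mask is padded with background (0).  Returns the padded arrays and
    b_ref translated into padded coordinates.
    """
    H, W = image.shape[:2]
    b_min = smallest_enclosing_2to1(b_ref)
    need_h = max(b_min.h - H, 0)
    need_w = max(b_min.w - W, 0)
    if need_h == 0 and need_w == 0:
        return image, mask, b_ref
    top, left = need_h // 2, need_w // 2
    bottom, right = need_h - top, need_w - left
    pad = ((top, bottom), (left, right))
    image = np.pad(image, pad + ((0, 0),) * (image.ndim - 2), mode="edge")
    if mask is not None:
        mask = np.pad(mask, pad, mode="constant", constant_values=0)
    b_ref = PixelBox(r0=b_ref.r0 + top, c0=b_ref.c0 + left, h=b_ref.h, w=b_ref.w)
    return image, mask, b_ref


def build_roi_context(
    masks: list[np.ndarray], image_h: int, image_w: int
) -> RoiContext:
    """Derive the per-video ROI bounds from all of the video's masks.

    When every mask is empty (the glottis never opens on camera) there is no
    reference box; we fall back to the centered largest in-image 2:1 box so
    the video stays usable.
    """
    boxes = [mask_bbox(m) for m in masks]
    boxes = [b for b in boxes if b is not None]
    if boxes:
        b_ref = combine_bboxes(boxes)
    else:
        w = max(min(image_w, image_h // 2), 1)
        b_ref = PixelBox(r0=(image_h - 2 * w) // 2, c0=(image_w - w) // 2, h=2 * w, w=w)
    b_min = smallest_enclosing_2to1(b_ref)
    b_max = largest_2to1_in_image(b_ref, image_h, image_w)
    if not b_min.within_image(image_h, image_w):
        # clamp the minimal box into the image where possible; callers that
        # padded beforehand never reach this branch
        r0 = min(max(b_min.r0, 0), max(image_h - b_min.h, 0))
        c0 = min(max(b_min.c0, 0), max(image_w - b_min.w, 0))
        b_min = PixelBox(r0=r0, c0=c0, h=b_min.h, w=b_min.w)
    return RoiContext(b_ref=b_ref, b_min=b_min, b_max=b_max, image_h=image_h, image_w=image_w)


def sample_roi(ctx: RoiContext, seed: int | np.random.Generator) -> PixelBox:
    """Draw a random 2:1 ROI containing b_ref and lying in-image.

    Width is uniform over feasible integer widths, then the position is
    uniform over feasible placements — the minimal-assumption reading of a
    "randomly chosen" box between the smallest and largest bounds.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w_lo, w_hi = ctx.b_min.w, ctx.b_max.w
    if w_hi < w_lo:
        w_lo = w_hi = ctx.b_min.w
    w = int(rng.integers(w_lo, w_hi + 1))
    h = 2 * w
    ref = ctx.b_ref

    def bounds(ref_start: int, ref_extent: int, size: int, limit: int) -> tuple[int, int]:
        lo = max(ref_start + ref_extent - size, 0)
        hi = min(ref_start, limit - size)
        if hi < lo:  # degenerate (box barely fits): pin to the clamped placement
            hi = lo = min(max(lo, 0), max(limit - size, 0))
        return lo, hi

    r_lo, r_hi = bounds(ref.r0, ref.h, h, ctx.image_h)
    c_lo, c_hi = bounds(ref.c0, ref.w, w, ctx.image_w)
    r0 = int(rng.integers(r_lo, r_hi + 1))
    c0 = int(rng.integers(c_lo, c_hi + 1))
    return PixelBox(r0=r0, c0=c0, h=h, w=w)


def _resize(arr: np.ndarray, target_h: int, target_w: int, *, nearest: bool) -> np.ndarray:
    mode = Image.NEAREST if nearest else Image.BILINEAR
    if arr.ndim == 2:
        im = Image.fromarray(arr)
        return np.asarray(im.resize((target_w, target_h), mode))
    chans = [
        np.asarray(Image.fromarray(arr[..., k]).resize((target_w, target_h), mode))
        for k in range(arr.shape[2])
    ]
    return np.stack(chans, axis=-1)


def crop_resize(
    image: np.ndarray,
    mask: np.ndarray | None,
    box: PixelBox,
    target_h: int,
    target_w: int,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Crop `box` from image (and mask) and resize to the target shape.

    The image is interpolated bilinearly, the mask by nearest neighbour and
    re-binarized, so mask values stay strictly {0, 1}.
    """
    if target_h != 2 * target_w:
        warnings.warn(
            f"target {target_h}x{target_w} is not 2:1 (height = 2 x width)",
            stacklevel=2,
        )
    H, W = image.shape[:2]
    if not box.within_image(H, W):
        raise ValueError(f"box {box} does not fit in image {H}x{W}")
    img_c = image[box.r0 : box.r1, box.c0 : box.c1]
    out_img = _resize(np.ascontiguousarray(img_c), target_h, target_w, nearest=False)
    out_mask = None
    if mask is not None:
        mask = _check_binary(mask)
        m_c = np.ascontiguousarray(mask[box.r0 : box.r1, box.c0 : box.c1]).astype(np.uint8)
        out_mask = _resize(m_c, target_h, target_w, nearest=True)
        out_mask = (out_mask > 0).astype(np.uint8)
    return out_img, out_mask


def legacy_resize(
    image: np.ndarray, mask: np.ndarray | None, target_h: int, target_w: int
) -> tuple[np.ndarray, np.ndarray | None]:
    """Whole-image anisotropic resize (the legacy method the ROI method replaces).

    Squeezing arbitrary aspect ratios into a fixed 2:1 input deforms the
    glottis; kept for comparison experiments.
    """
    H, W = image.shape[:2]
    box = PixelBox(r0=0, c0=0, h=H, w=W)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return crop_resize(image, mask, box, target_h, target_w)
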