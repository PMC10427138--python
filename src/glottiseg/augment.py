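"""Per-epoch stochastic augmentation of image/mask pairs.

Operations and firing probabilities follow the training protocol: brightness
and contrast (p = 0.75), gamma (p = 0.75), Gaussian noise (p = 0.5),
blurring (p = 0.5), rotation between 0° and 30° (p = 0.75) with a random
direction, and horizontal mirroring (p = 0.5).  Geometric operations are
applied identically to image and mask; photometric operations touch the
image only, so the mask array is bit-identical through them.

Augmentation plans are drawn separately from their application
(:func:`draw_plan` / :func:`apply_plan`) so a training loop can log or
replay the exact epoch augmentations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["AugmentationConfig", "AugmentationPlan", "draw_plan", "apply_plan", "augment_pair"]


@dataclass(frozen=True)
class AugmentationConfig:
    p_brightness_contrast: float = 0.75
    p_gamma: float = 0.75
    p_noise: float = 0.5
    p_blur: float = 0.5
    p_rotate: float = 0.75
    p_hflip: float = 0.5
    # magnitude ranges (the protocol names only the augmentation package's
    # defaults; these mirror them and are overridable)
    brightness_limit: float = 0.2
    contrast_limit: float = 0.2
    gamma_range: tuple[float, float] = (0.7, 1.3)
    noise_sd_max: float = 10.0
    blur_sigma_max: float = 2.0
    rotate_range_deg: tuple[float, float] = (0.0, 30.0)

    def __post_init__(self) -> None:
        for name in ("p_brightness_contrast", "p_gamma", "p_noise", "p_blur", "p_rotate", "p_hflip"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")

    @classmethod
    def disabled(cls) -> "AugmentationConfig":
        return cls(p_brightness_contrast=0, p_gamma=0, p_noise=0, p_blur=0, p_rotate=0, p_hflip=0)


@dataclass(frozen=True)
class AugmentationPlan:
    """Concrete draw of which ops fire and with what magnitudes."""

    brightness: float | None = None  # additive shift as fraction of 255
    contrast: float | None = None  # multiplicative deviation from 1
    gamma: float | None = None
    noise_sd: float | None = None
    noise_seed: int | None = None
    blur_sigma: float | None = None
    rotate_deg: float | None = None
    hflip: bool = False


def draw_plan(cfg: AugmentationConfig, rng: np.random.Generator) -> AugmentationPlan:
    """Draw one augmentation plan; every random decision flows through rng."""
    kw: dict = {}
    if rng.random() < cfg.p_brightness_contrast:
        kw["brightness"] = float(rng.uniform(-cfg.brightness_limit, cfg.brightness_limit))
        kw["contrast"] = float(rng.uniform(-cfg.contrast_limit, cfg.contrast_limit))
    if rng.random() < cfg.p_gamma:
        kw["gamma"] = float(rng.uniform(*cfg.gamma_range))
    if rng.random() < cfg.p_noise:
        kw["noise_sd"] = float(rng.uniform(0.0, cfg.noise_sd_max))
        kw["noise_seed"] = int(rng.integers(0, 2**31))
    if rng.random() < cfg.p_blur:
        kw["blur_sigma"] = float(rng.uniform(0.0, cfg.blur_sigma_max))
    if rng.random() < cfg.p_rotate:
        angle = float(rng.uniform(*cfg.rotate_range_deg))
        sign = 1.0 if rng.random() < 0.5 else -1.0  # symmetric: no lateral bias
        kw["rotate_deg"] = sign * angle
    if rng.random() < cfg.p_hflip:
        kw["hflip"] = True
    return AugmentationPlan(**kw)


def apply_plan(
    image: np.ndarray, mask: np.ndarray, plan: AugmentationPlan
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a plan; returns new arrays (inputs untouched)."""
    if image.shape[:2] != mask.shape:
        raise ValueError(f"image {image.shape} vs mask {mask.shape}")
    img = image.astype(np.float64)
    msk = mask

    # --- geometric (identical on image and mask) ---
    if plan.rotate_deg is not None and plan.rotate_deg != 0.0:
        img = ndimage.rotate(img, plan.rotate_deg, reshape=False, order=1, mode="nearest")
        msk = ndimage.rotate(
            msk.astype(np.float64), plan.rotate_deg, reshape=False, order=0,
            mode="constant", cval=0.0,
        )
        msk = (msk >= 0.5).astype(np.uint8)
    if plan.hflip:
        img = img[:, ::-1].copy()
        msk = msk[:, ::-1].copy()

    # --- photometric (image only) ---
    if plan.contrast is not None:
        img = (img - 127.5) * (1.0 + plan.contrast) + 127.5
    if plan.brightness is not None:
        img = img + plan.brightness * 255.0
    if plan.gamma is not None:
        img = np.clip(img, 0.0, 255.0)
        img = ((img / 255.0) ** plan.gamma) * 255.0
    if plan.blur_sigma is not None and plan.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=plan.blur_sigma, mode="nearest")
    if plan.noise_sd is not None and plan.noise_sd > 0:
        noise_rng = np.random.default_rng(plan.noise_seed)
        img = img + noise_rng.normal(0.0, plan.noise_sd, size=img.shape)

    img = np.clip(img, 0.0, 255.0)
    if image.dtype == np.uint8:
        img = np.rint(img).astype(np.uint8)
    else:
        img = img.astype(image.dtype)
    if msk is mask:
        msk = mask.copy()
    return img, msk


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    cfg: AugmentationConfig,
    rng_state: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw and apply one augmentation; deterministic under rng_state."""
    rng = (
        rng_state
        if isinstance(rng_state, np.random.Generator)
        else np.random.default_rng(rng_state)
    )
    return apply_plan(image, mask, draw_plan(cfg, rng))
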