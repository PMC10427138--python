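"""Synthetic laryngeal high-speed-video generator with exact ground truth.

Each video shows a vertically elongated elliptical glottal gap, darker than
the surrounding tissue, whose area follows a rectified sinusoid over the
frames — open phases where the vocal folds separate and closed phases where
the mask is empty, like one phonatory cycle seen from above.  "Camera
domains" differ photometrically (resolution, brightness, contrast, noise,
blur, vignetting and an optional honeycomb fiber-optic lattice, the
signature artifact of flexible endoscopes), which provides controllable
concept shift between corpora.

The mask is the analytic ellipse membership rendered before any photometric
corruption, so ground truth is exact by construction and invariant to the
photometric parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["DomainSpec", "VideoSample", "generate_video", "generate_corpus"]


@dataclass(frozen=True)
class DomainSpec:
    """One synthetic camera domain.

    Intensity parameters are 8-bit gray values; the glottal gap renders at
    ``background_level - glottis_contrast`` (the gap is darker than tissue,
    as in endoscopic views).  ``max_open_area_frac`` is the peak gap area as
    a fraction of the image; ``oscillation_freq`` counts open/close cycles
    per video.
    """

    name: str
    height: int = 128
    width: int = 96
    background_level: float = 180.0
    glottis_contrast: float = 120.0
    noise_sd: float = 4.0
    blur_sigma: float = 0.5
    vignette_strength: float = 0.15
    honeycomb: bool = False
    honeycomb_pitch: int = 8
    honeycomb_strength: float = 0.6
    oscillation_freq: float = 2.0
    max_open_area_frac: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError(f"domain {self.name!r}: height/width must be >= 16")
        if not 0.0 < self.max_open_area_frac <= 0.25:
            raise ValueError("max_open_area_frac must lie in (0, 0.25]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.vignette_strength <= 1.0:
            raise ValueError("vignette_strength must lie in [0, 1]")


@dataclass(frozen=True)
class VideoSample:
    """One recording: frames, exact binary masks, and its camera tag."""

    frames: list[np.ndarray]
    masks: list[np.ndarray]
    domain_name: str
    video_id: str

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.masks):
            raise ValueError("frames and masks must have equal length")


def _ellipse_mask(
    h: int, w: int, cy: float, cx: float, a: float, b: float, tilt: float
) -> np.ndarray:
    """Exact pixel membership of a tilted ellipse with semi-axes a (rows), b (cols)."""
    if a <= 0.5 or b <= 0.5:
        return np.zeros((h, w), dtype=np.uint8)
    rr, cc = np.mgrid[0:h, 0:w]
    dy = rr - cy
    dx = cc - cx
    ct, st = np.cos(tilt), np.sin(tilt)
    u = ct * dy + st * dx
    v = -st * dy + ct * dx
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def _honeycomb_overlay(h: int, w: int, pitch: int, strength: float = 0.6) -> np.ndarray:
    """Multiplicative fiber-bundle lattice in (0, 1]; darkens along a
    triangular grid with the given cell pitch (never brightens)."""
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    # three plane waves at 60 degrees -> hexagonal interference pattern;
    # the doubled wavenumber makes `pitch` the exact lattice period along
    # the image axes (every component frequency is a multiple of 1/pitch)
    k = 4.0 * np.pi / pitch
    s = (
        np.cos(k * cc)
        + np.cos(k * (0.5 * cc + np.sqrt(3.0) / 2.0 * rr))
        + np.cos(k * (0.5 * cc - np.sqrt(3.0) / 2.0 * rr))
    )
    lattice = (3.0 - s) / 6.0  # 0 at cell centers, 1 between cells
    return 1.0 - strength * lattice**2


def _vignette(h: int, w: int, strength: float) -> np.ndarray:
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    ry = (rr - (h - 1) / 2.0) / (h / 2.0)
    rx = (cc - (w - 1) / 2.0) / (w / 2.0)
    return 1.0 - strength * (ry**2 + rx**2) / 2.0


def _gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return img
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(img, sigma=sigma, mode="nearest")


def generate_video(spec: DomainSpec, n_frames: int, seed: int) -> VideoSample:
    """Render one synthetic video of ``n_frames`` frames.

    The glottal gap is an ellipse with aspect >= 2 (taller than wide) whose
    semi-axes scale with ``max(0, sin(2π f t / n_frames))`` — the closed
    phase of the cycle gives all-zero masks.  Identical (spec, n_frames,
    seed) reproduce bit-identical output.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    h, w = spec.height, spec.width
    rng = np.random.default_rng(np.random.SeedSequence([seed, spec.seed]))

    # per-video geometry: peak semi-axes from the target open-area fraction,
    # a/b >= 2 so the gap is elongated along the image rows
    aspect = rng.uniform(2.5, 4.0)
    peak_area = spec.max_open_area_frac * h * w
    b_peak = np.sqrt(peak_area / (np.pi * aspect))
    a_peak = aspect * b_peak
    cy = h / 2.0 + rng.uniform(-0.12, 0.12) * h
    cx = w / 2.0 + rng.uniform(-0.12, 0.12) * w
    tilt = rng.uniform(-0.15, 0.15)
    phase = rng.uniform(0.0, 2.0 * np.pi)

    vign = _vignette(h, w, spec.vignette_strength)
    comb = (
        _honeycomb_overlay(h, w, spec.honeycomb_pitch, spec.honeycomb_strength)
        if spec.honeycomb
        else None
    )
    # smooth per-video tissue texture, fixed across frames
    texture = _gaussian_blur(rng.normal(0.0, 12.0, size=(h, w)), 4.0)

    frames: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for t in range(n_frames):
        osc = np.sin(2.0 * np.pi * spec.oscillation_freq * t / n_frames + phase)
        open_frac = max(osc, 0.0)
        mask = _ellipse_mask(h, w, cy, cx, a_peak * open_frac, b_peak * open_frac, tilt)

        img = np.full((h, w), spec.background_level, dtype=np.float64) + texture
        img[mask == 1] = spec.background_level - spec.glottis_contrast
        img = _gaussian_blur(img, spec.blur_sigma)
        img *= vign
        if comb is not None:
            img *= comb
        img += rng.normal(0.0, spec.noise_sd, size=(h, w))
        frames.append(np.clip(img, 0.0, 255.0).astype(np.uint8))
        masks.append(mask)

    if not any(m.any() for m in masks):
        # guarantee at least one open frame: re-render the peak phase frame
        t_peak = int(np.argmax([np.sin(2.0 * np.pi * spec.oscillation_freq * t / n_frames + phase) for t in range(n_frames)]))
        mask = _ellipse_mask(h, w, cy, cx, a_peak, b_peak, tilt)
        img = np.full((h, w), spec.background_level, dtype=np.float64) + texture
        img[mask == 1] = spec.background_level - spec.glottis_contrast
        img = _gaussian_blur(img, spec.blur_sigma)
        img *= vign
        if comb is not None:
            img *= comb
        img += rng.normal(0.0, spec.noise_sd, size=(h, w))
        frames[t_peak] = np.clip(img, 0.0, 255.0).astype(np.uint8)
        masks[t_peak] = mask

    return VideoSample(frames=frames, masks=masks, domain_name=spec.name, video_id="")


def generate_corpus(
    domains: list[DomainSpec],
    videos_per_domain: int,
    frames_per_video: int,
    seed: int,
) -> list[VideoSample]:
    """Generate ``videos_per_domain`` videos for each camera domain.

    Per-video seeds derive deterministically from the corpus seed, so the
    corpus is reproducible as a whole and each video individually.
    """
    if not domains:
        raise ValueError("need at least one domain")
    samples: list[VideoSample] = []
    for d_idx, spec in enumerate(domains):
        for v_idx in range(videos_per_domain):
            video_seed = int(
                np.random.SeedSequence([seed, d_idx, v_idx]).generate_state(1)[0] % (2**31)
            )
            vs = generate_video(spec, frames_per_video, video_seed)
            vid = f"{spec.name}_v{v_idx:03d}"
            samples.append(replace(vs, video_id=vid))
    return samples
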