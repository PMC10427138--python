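"""Reading and writing BAGLS-style frame datasets, splits, and batch draws.

Layout dialect: ``<video_id>/<frame_idx>.png`` paired with
``<video_id>/<frame_idx>_seg.png`` plus a per-video ``meta.json`` holding
the camera/domain tag.  Masks are stored as {0, 255} PNGs and mapped to
{0, 1} in memory.

Splitting and batch drawing operate at video granularity: frames within one
recording are near-duplicates, so frame-level splits would leak test
content into training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .synthetic import VideoSample

__all__ = [
    "FrameRecord",
    "DatasetSplit",
    "BatchSchedule",
    "Frame",
    "write_corpus",
    "load_dataset",
    "load_frames",
    "split_train_val_test",
    "draw_batches",
    "records_to_manifest",
]


@dataclass(frozen=True)
class FrameRecord:
    """One annotated frame on disk: image path, mask path, and provenance."""

    image_path: Path
    mask_path: Path
    video_id: str
    domain_name: str


@dataclass(frozen=True)
class Frame:
    """One annotated frame in memory (8-bit grayscale image, binary mask)."""

    image: np.ndarray
    mask: np.ndarray
    video_id: str
    domain_name: str


@dataclass(frozen=True)
class DatasetSplit:
    train: list[FrameRecord]
    val: list[FrameRecord]
    test: list[FrameRecord]


@dataclass(frozen=True)
class BatchSchedule:
    """Equal batch fractions of the new-data training set, summing to 1.

    ``BatchSchedule.from_b(0.25)`` gives four 25% batches — the incremental
    schedules used in the re-training experiments (b in {25%, 50%, 75%, 100%}).
    """

    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ValueError("schedule must contain at least one fraction")
        if any(f <= 0 or f > 1 for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(self.fractions)}")

    @classmethod
    def from_b(cls, b: float) -> "BatchSchedule":
        n = round(1.0 / b)
        if abs(n * b - 1.0) > 1e-9:
            raise ValueError(f"batch fraction {b} does not evenly divide 1")
        return cls(fractions=(b,) * n)

    @property
    def n_batches(self) -> int:
        return len(self.fractions)


def write_corpus(samples: list[VideoSample], root_dir: str | Path) -> list[FrameRecord]:
    """Write videos in the BAGLS-style layout; returns the written manifest."""
    root = Path(root_dir)
    records: list[FrameRecord] = []
    for vs in samples:
        vdir = root / vs.video_id
        vdir.mkdir(parents=True, exist_ok=True)
        (vdir / "meta.json").write_text(
            json.dumps({"video_id": vs.video_id, "domain_name": vs.domain_name}, indent=1)
        )
        for idx, (img, msk) in enumerate(zip(vs.frames, vs.masks)):
            ip = vdir / f"{idx}.png"
            mp = vdir / f"{idx}_seg.png"
            Image.fromarray(img).save(ip)
            Image.fromarray((msk * 255).astype(np.uint8)).save(mp)
            records.append(
                FrameRecord(image_path=ip, mask_path=mp, video_id=vs.video_id, domain_name=vs.domain_name)
            )
    return records


def load_dataset(root_dir: str | Path) -> list[FrameRecord]:
    """Scan a BAGLS-style tree into frame records, deterministically ordered.

    Raises if an image lacks its ``_seg`` partner or a mask is non-binary.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    records: list[FrameRecord] = []
    for vdir in sorted(p for p in root.iterdir() if p.is_dir()):
        meta_path = vdir / "meta.json"
        domain = "unknown"
        if meta_path.exists():
            domain = json.loads(meta_path.read_text()).get("domain_name", "unknown")
        images = sorted(
            (p for p in vdir.glob("*.png") if not p.stem.endswith("_seg")),
            key=lambda p: (len(p.stem), p.stem),
        )
        for ip in images:
            mp = vdir / f"{ip.stem}_seg.png"
            if not mp.exists():
                raise FileNotFoundError(f"image {ip} has no mask partner {mp.name}")
            records.append(
                FrameRecord(image_path=ip, mask_path=mp, video_id=vdir.name, domain_name=domain)
            )
    return records


def _load_mask(path: Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    vals = np.unique(arr)
    if not np.isin(vals, (0, 255)).all():
        raise ValueError(f"mask {path} is not binary (values {vals[:10]})")
    return (arr > 0).astype(np.uint8)


def load_frames(records: list[FrameRecord]) -> list[Frame]:
    """Decode records into memory (grayscale image + {0,1} mask)."""
    frames = []
    for rec in records:
        img = np.asarray(Image.open(rec.image_path).convert("L"))
        msk = _load_mask(rec.mask_path)
        if img.shape != msk.shape:
            raise ValueError(f"{rec.image_path}: image {img.shape} vs mask {msk.shape}")
        frames.append(Frame(image=img, mask=msk, video_id=rec.video_id, domain_name=rec.domain_name))
    return frames


def frames_from_samples(samples: list[VideoSample]) -> list[Frame]:
    """In-memory path from the synthetic generator, bypassing disk."""
    return [
        Frame(image=img, mask=msk, video_id=vs.video_id, domain_name=vs.domain_name)
        for vs in samples
        for img, msk in zip(vs.frames, vs.masks)
    ]


def _videos_in_order(records: list[FrameRecord]) -> list[str]:
    seen: dict[str, None] = {}
    for r in records:
        seen.setdefault(r.video_id, None)
    return list(seen)


def split_train_val_test(
    records: list[FrameRecord],
    val_frac: float,
    test_videos: list[str],
    seed: int,
) -> DatasetSplit:
    """Video-level split: named test videos out, then ~5% of the remaining
    videos (``round(val_frac * n)``) drawn for validation."""
    if not 0.0 < val_frac < 1.0:
        raise ValueError(f"val_frac must lie in (0, 1), got {val_frac}")
    vids = _videos_in_order(records)
    missing = set(test_videos) - set(vids)
    if missing:
        raise ValueError(f"test videos not present in records: {sorted(missing)}")
    test_set = set(test_videos)
    pool = [v for v in vids if v not in test_set]
    rng = np.random.default_rng(seed)
    n_val = int(round(val_frac * len(pool)))
    val_ids = set(rng.choice(pool, size=n_val, replace=False)) if n_val else set()
    by_split = lambda pred: [r for r in records if pred(r.video_id)]
    return DatasetSplit(
        train=by_split(lambda v: v not in test_set and v not in val_ids),
        val=by_split(lambda v: v in val_ids),
        test=by_split(lambda v: v in test_set),
    )


def draw_batches(
    records: list[FrameRecord], schedule: BatchSchedule, seed: int
) -> list[list[FrameRecord]]:
    """Partition records into the schedule's batches at video granularity.

    Videos are shuffled once and dealt out so batch video counts match the
    fractions within one video; batches are disjoint and exhaust the input.
    """
    vids = _videos_in_order(records)
    if len(vids) < schedule.n_batches:
        raise ValueError(
            f"{len(vids)} videos cannot fill {schedule.n_batches} disjoint batches"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(vids))
    n = len(order)
    batches: list[list[FrameRecord]] = []
    start = 0
    cum = 0.0
    for i, frac in enumerate(schedule.fractions):
        cum += frac
        stop = n if i == schedule.n_batches - 1 else int(round(cum * n))
        stop = max(stop, start + 1)
        chosen = set(order[start:stop])
        batches.append([r for r in records if r.video_id in chosen])
        start = stop
    return batches


def records_to_manifest(records: list[FrameRecord]) -> pd.DataFrame:
    """CSV-exportable manifest of frame records."""
    return pd.DataFrame(
        {
            "image_path": [str(r.image_path) for r in records],
            "mask_path": [str(r.mask_path) for r in records],
            "video_id": [r.video_id for r in records],
            "domain_name": [r.domain_name for r in records],
        }
    )
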