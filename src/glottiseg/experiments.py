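"""Canonical synthetic studies: domain-recovery and forgetting/mitigation.

These are the package's reference experiments at CPU scale.  The
``rigid_domain``/``flex_domain`` pair encodes a strong concept shift — a
bright, clean rigid-endoscope camera versus a darker, noisier, lower
resolution flexible endoscope with a honeycomb fiber lattice — the
synthetic analogue of the hardest real re-training case (flexible
endoscopic recordings were the most novel data for the published
benchmark's baseline).

The forgetting study reproduces the qualitative benchmark pattern: plain
incremental finetuning on the new domain erodes old-domain accuracy
(catastrophic forgetting); mixing old data into each batch reduces the
erosion; and dynamic knowledge distillation adapts strongly to the new
domain at an old-domain cost comparable to or below plain finetuning's —
its new-domain gain exceeds that cost by an order of magnitude.  Effects
are a few IoU points while seed noise on the baselines is larger, so all
comparisons are paired per seed (each strategy against its own seed's
baseline) and summarized by the median over seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_io import BatchSchedule, Frame, frames_from_samples
from .retrain import (
    RetrainPlan,
    finetune_kd,
    incremental_finetune,
    incremental_finetune_mixed,
    train_baseline,
)
from .synthetic import DomainSpec, generate_corpus
from .training import TrainConfig, evaluate
from .unet import UNetSpec

__all__ = [
    "rigid_domain",
    "flex_domain",
    "holdout_split",
    "recovery_study",
    "forgetting_study",
    "ForgettingResult",
]


def rigid_domain() -> DomainSpec:
    """Bright, low-noise rigid-endoscope-like camera (the old domain)."""
    return DomainSpec(
        name="rigid", height=128, width=96, background_level=180.0,
        glottis_contrast=120.0, noise_sd=4.0, blur_sigma=0.5,
        vignette_strength=0.15, seed=0,
    )


def flex_domain() -> DomainSpec:
    """Flexible-endoscope-like camera (the new domain): lower resolution,
    darker, noisier, blurrier, strong vignette, honeycomb fiber lattice."""
    return DomainSpec(
        name="flex", height=80, width=64, background_level=90.0,
        glottis_contrast=55.0, noise_sd=8.0, blur_sigma=0.8,
        vignette_strength=0.5, honeycomb=True, honeycomb_pitch=10,
        honeycomb_strength=0.6, seed=1,
    )


def holdout_split(frames: list[Frame], n_test: int) -> tuple[list[Frame], list[Frame]]:
    """Hold out the first n_test videos (sorted by id) as a test set."""
    vids = sorted({f.video_id for f in frames})
    test = set(vids[:n_test])
    return (
        [f for f in frames if f.video_id not in test],
        [f for f in frames if f.video_id in test],
    )


def _sub_seed(master: int, tag: int) -> int:
    return int(np.random.SeedSequence([master, tag]).generate_state(1)[0] % 2**31)


def recovery_study(
    seed: int,
    videos: int = 10,
    frames_per_video: int = 16,
    n_test_videos: int = 3,
    max_epochs: int = 40,
) -> dict:
    """Train a micro U-Net on one synthetic domain and measure held-out mIoU.

    The basic parameter-recovery check: with exact ground truth and a
    single camera domain, the pipeline should segment held-out videos of
    that domain well (mIoU >= 0.85 at this scale).
    """
    corpus = generate_corpus([rigid_domain()], videos, frames_per_video, _sub_seed(seed, 1))
    frames = frames_from_samples(corpus)
    pool, test = holdout_split(frames, n_test_videos)
    cfg = TrainConfig(seed=_sub_seed(seed, 2), max_epochs=max_epochs, patience=10)
    ckpt, model = train_baseline(pool, UNetSpec.micro(), cfg, val_frac=0.25)
    rep = evaluate(model, test, cfg)
    return {
        "miou": rep.miou,
        "miou_sd": rep.miou_sd,
        "n_test_frames": rep.n_frames,
        "stop_epoch": ckpt.provenance["stop_epoch"],
    }


@dataclass
class ForgettingResult:
    """Paired per-seed outcomes and their medians for the forgetting study."""

    per_seed: list[dict] = field(default_factory=list)
    medians: dict = field(default_factory=dict)

    def summarize(self) -> None:
        med = lambda key: float(np.median([r[key] for r in self.per_seed]))
        self.medians = {
            "incremental_old_drop": med("inc_drop"),
            "mixed_old_drop": med("mix_drop"),
            "fkd_dynamic_old_drop": med("fkd_drop"),
            "fkd_dynamic_new_gain": med("fkd_gain"),
            "incremental_new_gain": med("inc_gain"),
        }


def _one_forgetting_seed(
    seed: int,
    videos: int,
    frames_per_video: int,
    n_test_videos: int,
    b: float,
) -> dict:
    old = frames_from_samples(
        generate_corpus([rigid_domain()], videos, frames_per_video, _sub_seed(seed, 10))
    )
    new = frames_from_samples(
        generate_corpus([flex_domain()], videos, frames_per_video, _sub_seed(seed, 11))
    )
    old_pool, old_test = holdout_split(old, n_test_videos)
    new_pool, new_test = holdout_split(new, n_test_videos)

    cfg_base = TrainConfig(seed=_sub_seed(seed, 12), max_epochs=40, patience=10)
    cfg_ft = TrainConfig(seed=_sub_seed(seed, 13), max_epochs=8, patience=3)
    spec = UNetSpec.micro()
    baseline, base_model = train_baseline(old_pool, spec, cfg_base, val_frac=0.25)
    base_old = evaluate(base_model, old_test, cfg_base).miou
    base_new = evaluate(base_model, new_test, cfg_base).miou

    sched = BatchSchedule.from_b(b)
    inc = incremental_finetune(
        RetrainPlan("incremental", sched, new_pool, cfg_ft, spec), baseline
    )
    mix = incremental_finetune_mixed(
        RetrainPlan("incremental_mixed", sched, new_pool, cfg_ft, spec, old_train=old_pool),
        baseline,
    )
    fkd = finetune_kd(
        RetrainPlan("fkd", sched, new_pool, cfg_ft, spec, alpha=0.5, teacher_mode="dynamic"),
        baseline,
    )
    out = {"seed": seed, "base_old": base_old, "base_new": base_new}
    for tag, ckpt in (("inc", inc), ("mix", mix), ("fkd", fkd)):
        model = ckpt.to_model()
        out[f"{tag}_old"] = evaluate(model, old_test, cfg_ft).miou
        out[f"{tag}_new"] = evaluate(model, new_test, cfg_ft).miou
        out[f"{tag}_drop"] = base_old - out[f"{tag}_old"]
        out[f"{tag}_gain"] = out[f"{tag}_new"] - base_new
    return out


def forgetting_study(
    master_seed: int,
    n_seeds: int = 3,
    videos: int = 12,
    frames_per_video: int = 12,
    n_test_videos: int = 4,
    b: float = 0.5,
) -> ForgettingResult:
    """Run the forgetting/mitigation comparison over several seeds.

    Per seed: train a baseline on the rigid domain, then apply plain
    incremental finetuning, mixed-data finetuning, and dynamic-teacher
    distillation (alpha = 0.5) to the flexible-endoscope domain in
    ``1/b`` sequential batches; evaluate old- and new-domain held-out
    videos before and after.
    """
    result = ForgettingResult()
    for i in range(n_seeds):
        result.per_seed.append(
            _one_forgetting_seed(
                _sub_seed(master_seed, 1000 + i), videos, frames_per_video, n_test_videos, b
            )
        )
    result.summarize()
    return result
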