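"""Re-training strategies for adapting a segmentation model to new cameras.

Four ways to absorb a new-domain corpus into an existing glottis model:

* **scratch** — retrain the whole network from a fresh initialization on
  all old data plus a fraction ``b`` of the new data;
* **incremental** — plain finetuning: warm-start from the baseline and
  train on disjoint new-data batches sequentially (risk: catastrophic
  forgetting of the old domain);
* **incremental_mixed** — as incremental, but every batch is topped up
  with an equal-sized share of old data to protect old-domain accuracy;
* **fkd** — finetuning with knowledge distillation: the student trains on
  new data against a blend of ground truth and a teacher model's soft
  predictions (weight ``alpha`` on the truth).  The teacher is either the
  frozen baseline (*static*) or replaced by the student after every batch
  (*dynamic*).

All strategies share the preprocessing, augmentation and epoch-seed
derivation, so outcome differences are attributable to the strategy alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentationConfig
from .dataset_io import BatchSchedule, Frame
from .metrics import EvaluationReport
from .training import TrainConfig, evaluate, train
from .unet import ModelCheckpoint, UNet, UNetSpec, build_unet

__all__ = [
    "RetrainPlan",
    "train_baseline",
    "retrain_from_scratch",
    "incremental_finetune",
    "incremental_finetune_mixed",
    "finetune_kd",
    "evaluate_per_group",
]

_STRATEGIES = ("scratch", "incremental", "incremental_mixed", "fkd")


@dataclass
class RetrainPlan:
    strategy: str
    schedule: BatchSchedule
    new_train: list[Frame]
    cfg: TrainConfig
    spec: UNetSpec = field(default_factory=UNetSpec.micro)
    old_train: list[Frame] = field(default_factory=list)
    alpha: float | None = None
    teacher_mode: str | None = None
    preprocessing: str = "roi"
    aug: AugmentationConfig | None = None
    val_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.strategy not in _STRATEGIES:
            raise ValueError(f"strategy must be one of {_STRATEGIES}")
        if self.strategy == "fkd":
            if self.teacher_mode not in ("static", "dynamic"):
                raise ValueError("fkd requires teacher_mode 'static' or 'dynamic'")
            if self.alpha is None:
                warnings.warn("alpha unset for fkd; defaulting to the balanced 0.5")
                self.alpha = 0.5
            if not 0.0 <= self.alpha <= 1.0:
                raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        elif self.teacher_mode is not None:
            raise ValueError("teacher_mode is only meaningful for the fkd strategy")


def _video_ids(frames: list[Frame]) -> list[str]:
    seen: dict[str, None] = {}
    for f in frames:
        seen.setdefault(f.video_id, None)
    return list(seen)


def _split_val(
    frames: list[Frame], val_frac: float, seed_seq: list[int]
) -> tuple[list[Frame], list[Frame]]:
    """Video-level validation carve-out: round(val_frac * n) videos, >= 1."""
    vids = _video_ids(frames)
    if len(vids) < 2:
        raise ValueError("need at least 2 videos to carve out validation data")
    rng = np.random.default_rng(np.random.SeedSequence(seed_seq))
    # floor of 2 val videos where possible: a single unrepresentative video
    # (e.g. mostly closed glottis) makes early stopping erratic
    floor = 2 if len(vids) >= 4 else 1
    n_val = min(max(floor, round(val_frac * len(vids))), len(vids) - 1)
    val_ids = set(rng.choice(vids, size=n_val, replace=False))
    tr = [f for f in frames if f.video_id not in val_ids]
    va = [f for f in frames if f.video_id in val_ids]
    return tr, va


def _draw_frame_batches(
    frames: list[Frame], schedule: BatchSchedule, seed_seq: list[int]
) -> list[list[Frame]]:
    """Disjoint video-level batches following the schedule fractions."""
    vids = _video_ids(frames)
    if len(vids) < schedule.n_batches:
        raise ValueError(f"{len(vids)} videos cannot fill {schedule.n_batches} batches")
    rng = np.random.default_rng(np.random.SeedSequence(seed_seq))
    order = list(rng.permutation(vids))
    n = len(order)
    out, start, cum = [], 0, 0.0
    for i, frac in enumerate(schedule.fractions):
        cum += frac
        stop = n if i == schedule.n_batches - 1 else max(int(round(cum * n)), start + 1)
        chosen = set(order[start:stop])
        out.append([f for f in frames if f.video_id in chosen])
        start = stop
    return out


def train_baseline(
    old_frames: list[Frame],
    spec: UNetSpec,
    cfg: TrainConfig,
    preprocessing: str = "roi",
    aug: AugmentationConfig | None = None,
    val_frac: float = 0.05,
) -> tuple[ModelCheckpoint, UNet]:
    """Train the initial model M0 on the old-domain corpus alone."""
    tr, va = _split_val(old_frames, val_frac, [cfg.seed, 555, 0])
    init_seed = int(np.random.SeedSequence([cfg.seed, 41]).generate_state(1)[0] % 2**31)
    model = build_unet(spec, init_seed)
    ckpt, _ = train(model, tr, va, cfg, preprocessing, aug, seed_tag=0)
    ckpt.provenance["strategy"] = "baseline"
    return ckpt, model


def retrain_from_scratch(plan: RetrainPlan) -> ModelCheckpoint:
    """Fresh initialization, trained on all old data + fraction b of new data.

    ``b`` is the first schedule fraction; validation holds out ~5% of each
    corpus.  With no new data at all this reduces exactly to baseline
    training (same seed, same checkpoint).
    """
    if plan.strategy != "scratch":
        raise ValueError("plan.strategy must be 'scratch'")
    cfg = plan.cfg
    old_tr, old_va = _split_val(plan.old_train, plan.val_frac, [cfg.seed, 555, 0])
    new_tr: list[Frame] = []
    new_va: list[Frame] = []
    if plan.new_train:
        subset = (
            plan.new_train
            if plan.schedule.n_batches == 1
            else _draw_frame_batches(plan.new_train, plan.schedule, [cfg.seed, 557])[0]
        )
        new_tr, new_va = _split_val(subset, plan.val_frac, [cfg.seed, 555, 1])
    init_seed = int(np.random.SeedSequence([cfg.seed, 41]).generate_state(1)[0] % 2**31)
    model = build_unet(plan.spec, init_seed)
    ckpt, _ = train(
        model, old_tr + new_tr, old_va + new_va, cfg, plan.preprocessing, plan.aug, seed_tag=0
    )
    ckpt.provenance["strategy"] = "scratch"
    return ckpt


def _finetune_steps(
    plan: RetrainPlan,
    baseline: ModelCheckpoint,
    mixed: bool,
    teacher_mode: str | None,
) -> ModelCheckpoint:
    cfg = plan.cfg
    model = baseline.to_model()
    teacher: UNet | None = None
    if teacher_mode is not None:
        teacher = baseline.to_model()
    batches = _draw_frame_batches(plan.new_train, plan.schedule, [cfg.seed, 557])
    old_pool = list(plan.old_train)
    for step, batch in enumerate(batches):
        if not batch:
            raise ValueError(f"finetuning batch {step} is empty")
        pool = batch
        if mixed:
            pool = batch + _old_share(old_pool, len(batch), [cfg.seed, 558, step])
        tr, va = _split_val(pool, plan.val_frac, [cfg.seed, 556, step])
        train(
            model,
            tr,
            va,
            cfg,
            plan.preprocessing,
            plan.aug,
            teacher=teacher,
            alpha=plan.alpha if plan.alpha is not None else 1.0,
            seed_tag=100 + step,
        )
        if teacher_mode == "dynamic":
            teacher = model.copy()
    ckpt = ModelCheckpoint.from_model(
        model,
        provenance={
            "strategy": plan.strategy,
            "schedule": list(plan.schedule.fractions),
            "alpha": plan.alpha,
            "teacher_mode": teacher_mode,
            "seed": cfg.seed,
        },
    )
    return ckpt


def _old_share(old_pool: list[Frame], n_frames: int, seed_seq: list[int]) -> list[Frame]:
    """Uniformly sampled old-domain share of exactly n_frames frames.

    Whole videos are drawn without replacement (with replacement plus a
    warning if the pool is too small) and the concatenation trimmed to the
    requested frame count.
    """
    if not old_pool:
        raise ValueError("mixed finetuning requires old-domain data")
    by_vid: dict[str, list[Frame]] = {}
    for f in old_pool:
        by_vid.setdefault(f.video_id, []).append(f)
    vids = list(by_vid)
    rng = np.random.default_rng(np.random.SeedSequence(seed_seq))
    order = list(rng.permutation(vids))
    share: list[Frame] = []
    i = 0
    while len(share) < n_frames:
        if i >= len(order):
            warnings.warn("old-data pool smaller than required share; sampling with replacement")
            order += list(rng.permutation(vids))
        share += by_vid[order[i]]
        i += 1
    return share[:n_frames]


def incremental_finetune(plan: RetrainPlan, baseline: ModelCheckpoint) -> ModelCheckpoint:
    """Sequential finetuning on disjoint new-data batches, warm-starting each
    step from the previous model (fresh optimizer and early-stopping state)."""
    if plan.strategy != "incremental":
        raise ValueError("plan.strategy must be 'incremental'")
    return _finetune_steps(plan, baseline, mixed=False, teacher_mode=None)


def incremental_finetune_mixed(plan: RetrainPlan, baseline: ModelCheckpoint) -> ModelCheckpoint:
    """Incremental finetuning where each batch is half new data, half an
    equal-sized uniformly sampled old-data share (forgetting mitigation)."""
    if plan.strategy != "incremental_mixed":
        raise ValueError("plan.strategy must be 'incremental_mixed'")
    return _finetune_steps(plan, baseline, mixed=True, teacher_mode=None)


def finetune_kd(plan: RetrainPlan, baseline: ModelCheckpoint) -> ModelCheckpoint:
    """Finetuning with knowledge distillation (static or dynamic teacher).

    The student minimizes alpha*Dice(student, truth) +
    (1-alpha)*Dice(student, teacher) on new-data batches; the teacher is
    never updated by student optimization.  With alpha = 1 this is exactly
    incremental finetuning; with one batch, static and dynamic coincide.
    """
    if plan.strategy != "fkd":
        raise ValueError("plan.strategy must be 'fkd'")
    return _finetune_steps(plan, baseline, mixed=False, teacher_mode=plan.teacher_mode)


def evaluate_per_group(
    model: UNet,
    frames: list[Frame],
    cfg: TrainConfig,
    preprocessing: str = "roi",
    baseline: UNet | None = None,
    groups: list[str] | None = None,
) -> list[EvaluationReport]:
    """One report per camera/domain tag plus a pooled report over all frames.

    With a baseline model given, each report carries the ΔmIoU against the
    baseline evaluated on the same frames.
    """
    if not frames:
        raise ValueError("no frames to evaluate")
    by_dom: dict[str, list[Frame]] = {}
    for f in frames:
        by_dom.setdefault(f.domain_name, []).append(f)
    if groups is not None:
        unknown = set(by_dom) - set(groups)
        if unknown:
            raise ValueError(f"unknown group keys: {sorted(unknown)}")
    reports = []
    for dom in sorted(by_dom):
        base_miou = None
        if baseline is not None:
            base_miou = evaluate(baseline, by_dom[dom], cfg, preprocessing).miou
        reports.append(
            evaluate(model, by_dom[dom], cfg, preprocessing, group_key=dom, baseline_miou=base_miou)
        )
    base_miou = evaluate(baseline, frames, cfg, preprocessing).miou if baseline else None
    reports.append(
        evaluate(model, frames, cfg, preprocessing, group_key="all", baseline_miou=base_miou)
    )
    return reports
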