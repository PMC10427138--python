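"""Training loop: cyclic learning rate, mini-batching, early stopping, k-fold CV.

Protocol: Adam with a triangular cyclic learning rate between 1e-6 and
1e-3, mini-batches of 8 images, at most 100 epochs with early stopping
when the validation Dice loss has not improved for 10 epochs, best-epoch
weights restored on stop.  Per epoch, ROIs are re-sampled and augmentations
re-drawn, so every epoch sees different training data; all draws derive
from (seed, epoch, frame index) and are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .augment import AugmentationConfig, augment_pair
from .dataset_io import Frame
from .metrics import EvaluationReport, dice_loss, dice_loss_grad, fkd_loss, fkd_loss_grad, iou
from .nn import Adam
from .roi import (
    RoiContext,
    build_roi_context,
    combine_bboxes,
    crop_resize,
    legacy_resize,
    mask_bbox,
    pad_to_fit_2to1,
    sample_roi,
    smallest_enclosing_2to1,
)
from .unet import ModelCheckpoint, UNet, UNetSpec, build_unet

__all__ = ["TrainConfig", "TrainHistory", "cyclic_lr", "train", "cross_validate", "evaluate"]


@dataclass(frozen=True)
class TrainConfig:
    lr_min: float = 1e-6
    lr_max: float = 1e-3
    step_size: int | None = None  # cyclic half-period in steps; None -> 4 epochs' worth
    minibatch_size: int = 8
    max_epochs: int = 100
    patience: int = 10
    improvement_tol: float = 1e-5  # float jitter must not reset patience
    input_h: int = 64
    input_w: int = 32
    threshold: float = 0.5
    roi_per_frame: bool = False  # default: one ROI per video per epoch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_min >= self.lr_max:
            raise ValueError("lr_min must be < lr_max")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr_trace: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    best_epoch: int = 0

    @property
    def best_val_loss(self) -> float:
        return self.val_loss[self.best_epoch - 1]


def cyclic_lr(global_step: int, cfg: TrainConfig, step_size: int | None = None) -> float:
    """Triangular wave: lr_min at step 0, lr_max at step_size, period 2*step_size."""
    if global_step < 0:
        raise ValueError("step must be >= 0")
    ss = step_size if step_size is not None else (cfg.step_size or 1)
    x = (global_step / ss) % 2.0
    tri = 1.0 - abs(x - 1.0)
    return cfg.lr_min + (cfg.lr_max - cfg.lr_min) * tri


# ---------------------------------------------------------------------------
# video grouping and preprocessing


@dataclass
class _VideoGroup:
    video_id: str
    domain_name: str
    frames: list[Frame]
    ctx: RoiContext


def _group_videos(frames: list[Frame]) -> list[_VideoGroup]:
    """Group frames by video, pad where the minimal 2:1 box overflows, and
    build each video's ROI context."""
    by_vid: dict[str, list[Frame]] = {}
    for f in frames:
        by_vid.setdefault(f.video_id, []).append(f)
    groups = []
    for vid in sorted(by_vid):
        vf = by_vid[vid]
        boxes = [b for b in (mask_bbox(f.mask) for f in vf) if b is not None]
        if boxes:
            b_ref = combine_bboxes(boxes)
            b_min = smallest_enclosing_2to1(b_ref)
            H, W = vf[0].image.shape[:2]
            if b_min.h > H or b_min.w > W:
                padded = []
                for f in vf:
                    img, msk, _ = pad_to_fit_2to1(f.image, f.mask, b_ref)
                    padded.append(replace(f, image=img, mask=msk))
                vf = padded
        H, W = vf[0].image.shape[:2]
        ctx = build_roi_context([f.mask for f in vf], H, W)
        groups.append(_VideoGroup(vid, vf[0].domain_name, vf, ctx))
    return groups


def _to_net_input(img: np.ndarray) -> np.ndarray:
    return img.astype(np.float32) / 255.0


def _preprocess_frame(
    frame: Frame, box, cfg: TrainConfig, preprocessing: str
) -> tuple[np.ndarray, np.ndarray]:
    if preprocessing == "roi":
        img, msk = crop_resize(frame.image, frame.mask, box, cfg.input_h, cfg.input_w)
    elif preprocessing == "legacy":
        img, msk = legacy_resize(frame.image, frame.mask, cfg.input_h, cfg.input_w)
    else:
        raise ValueError(f"unknown preprocessing mode {preprocessing!r}")
    return img, msk


def _eval_arrays(
    frames: list[Frame], cfg: TrainConfig, preprocessing: str
) -> tuple[np.ndarray, np.ndarray, list[Frame]]:
    """Deterministic evaluation preprocessing: the minimal 2:1 crop (ROI mode)
    or the whole-image resize (legacy)."""
    xs, ts, order = [], [], []
    for g in _group_videos(frames):
        for f in g.frames:
            img, msk = _preprocess_frame(f, g.ctx.b_min, cfg, preprocessing)
            xs.append(_to_net_input(img))
            ts.append(msk.astype(np.float32))
            order.append(f)
    return np.stack(xs), np.stack(ts), order


def _batched_forward(model: UNet, x: np.ndarray, batch: int) -> np.ndarray:
    outs = [model.forward(x[i : i + batch]) for i in range(0, len(x), batch)]
    return np.concatenate(outs, axis=0)


def train(
    model: UNet,
    train_frames: list[Frame],
    val_frames: list[Frame],
    cfg: TrainConfig,
    preprocessing: str = "roi",
    aug: AugmentationConfig | None = None,
    teacher: UNet | None = None,
    alpha: float = 1.0,
    teacher_binarize: bool = False,
    seed_tag: int = 0,
) -> tuple[ModelCheckpoint, TrainHistory]:
    """Train `model` in place; returns the best-validation checkpoint + history.

    With `teacher` set, the loss becomes the knowledge-distillation blend
    alpha*Dice(student, truth) + (1-alpha)*Dice(student, teacher); the
    teacher is only ever run forward, never updated.  Validation always
    monitors the plain Dice loss against ground truth.

    `seed_tag` namespaces the epoch-seed stream (e.g. a CV fold index) so
    parallel trainings from one master seed stay decorrelated.
    """
    if not train_frames:
        raise ValueError("empty training set")
    if not val_frames:
        raise ValueError("empty validation set")
    aug = aug if aug is not None else AugmentationConfig()
    groups = _group_videos(train_frames)
    val_x, val_t, _ = _eval_arrays(val_frames, cfg, preprocessing)

    n_train = len(train_frames)
    steps_per_epoch = max(1, math.ceil(n_train / cfg.minibatch_size))
    step_size = cfg.step_size or 4 * steps_per_epoch

    opt = Adam()
    history = TrainHistory()
    best_state = model.state_arrays()
    best_loss = math.inf
    bad_epochs = 0
    global_step = 0

    for epoch in range(1, cfg.max_epochs + 1):
        epoch_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, seed_tag, epoch]))
        xs, ts = [], []
        fidx = 0
        for g in groups:
            vid_box = None
            if preprocessing == "roi" and not cfg.roi_per_frame:
                vid_box = sample_roi(g.ctx, np.random.default_rng(
                    np.random.SeedSequence([cfg.seed, seed_tag, epoch, 11, fidx])))
            for f in g.frames:
                frame_ss = np.random.SeedSequence([cfg.seed, seed_tag, epoch, 13, fidx])
                frame_rng = np.random.default_rng(frame_ss)
                box = vid_box
                if preprocessing == "roi" and cfg.roi_per_frame:
                    box = sample_roi(g.ctx, frame_rng)
                img, msk = _preprocess_frame(f, box, cfg, preprocessing)
                img, msk = augment_pair(img, msk, aug, frame_rng)
                xs.append(_to_net_input(img))
                ts.append(msk.astype(np.float32))
                fidx += 1
        X = np.stack(xs)
        T = np.stack(ts)
        order = epoch_rng.permutation(len(X))

        ep_losses = []
        for start in range(0, len(X), cfg.minibatch_size):
            sel = order[start : start + cfg.minibatch_size]
            xb, tb = X[sel], T[sel]
            prob = model.forward(xb)
            teach_b = None
            if teacher is not None:
                teach_b = teacher.forward(xb)
                if teacher_binarize:
                    teach_b = (teach_b >= cfg.threshold).astype(np.float32)
            # soft Dice over the whole mini-batch: closed-glottis frames are
            # balanced by open ones instead of each saturating the loss at 1
            if teach_b is None:
                loss = dice_loss(prob, tb)
                dprob = dice_loss_grad(prob, tb)
            else:
                loss = fkd_loss(prob, tb, teach_b, alpha)
                dprob = fkd_loss_grad(prob, tb, teach_b, alpha)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {global_step}"
                )
            model.backward(dprob)
            lr = cyclic_lr(global_step, cfg, step_size)
            opt.step(model.params(), lr)
            history.lr_trace.append(lr)
            ep_losses.append(loss)
            global_step += 1

        vprob = _batched_forward(model, val_x, cfg.minibatch_size)
        # early stopping monitors the Dice loss against ground truth,
        # aggregated over the whole val set (also under distillation)
        vloss = dice_loss(vprob, val_t)
        if not math.isfinite(vloss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.train_loss.append(float(np.mean(ep_losses)))
        history.val_loss.append(vloss)

        if vloss < best_loss - cfg.improvement_tol:
            best_loss = vloss
            best_state = model.state_arrays()
            history.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
        history.stop_epoch = epoch
        if bad_epochs >= cfg.patience:
            break

    model.load_state(best_state)
    ckpt = ModelCheckpoint.from_model(
        model,
        provenance={
            "seed": cfg.seed,
            "seed_tag": seed_tag,
            "preprocessing": preprocessing,
            "stop_epoch": history.stop_epoch,
            "best_epoch": history.best_epoch,
            "n_train_frames": n_train,
        },
    )
    return ckpt, history


def evaluate(
    model: UNet,
    frames: list[Frame],
    cfg: TrainConfig,
    preprocessing: str = "roi",
    group_key: str = "all",
    baseline_miou: float | None = None,
) -> EvaluationReport:
    """Per-frame IoU of thresholded predictions on deterministically
    preprocessed frames."""
    if not frames:
        raise ValueError("empty evaluation set")
    x, t, _ = _eval_arrays(frames, cfg, preprocessing)
    prob = _batched_forward(model, x, cfg.minibatch_size)
    pred = (prob >= cfg.threshold).astype(np.uint8)
    ious = [iou(pred[i], t[i].astype(np.uint8)) for i in range(len(x))]
    return EvaluationReport(per_frame_iou=ious, group_key=group_key, baseline_miou=baseline_miou)


def _video_ids(frames: list[Frame]) -> list[str]:
    seen: dict[str, None] = {}
    for f in frames:
        seen.setdefault(f.video_id, None)
    return list(seen)


def cross_validate(
    frames: list[Frame],
    k: int,
    spec: UNetSpec,
    cfg: TrainConfig,
    preprocessing: str = "roi",
    aug: AugmentationConfig | None = None,
    val_frac: float = 0.05,
) -> list[EvaluationReport]:
    """k-fold cross-validation at video granularity.

    Each fold trains a fresh model (per-fold seed derived from the master
    seed) on the other folds, carving ~5% of its training videos out for
    validation, and reports IoU on the held-out fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    vids = _video_ids(frames)
    if len(vids) < k:
        raise ValueError(f"{len(vids)} videos cannot form {k} folds")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 99]))
    order = list(rng.permutation(vids))
    folds = [order[i::k] for i in range(k)]
    reports = []
    for i, fold in enumerate(folds):
        fold_set = set(fold)
        rest_vids = [v for v in order if v not in fold_set]
        n_val = max(1, round(val_frac * len(rest_vids)))
        fold_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 99, i]))
        val_ids = set(fold_rng.choice(rest_vids, size=n_val, replace=False))
        tr = [f for f in frames if f.video_id in set(rest_vids) - val_ids]
        va = [f for f in frames if f.video_id in val_ids]
        te = [f for f in frames if f.video_id in fold_set]
        fold_seed = int(np.random.SeedSequence([cfg.seed, 7, i]).generate_state(1)[0] % 2**31)
        model = build_unet(spec, fold_seed)
        train(model, tr, va, replace(cfg, seed=cfg.seed), preprocessing, aug, seed_tag=i + 1)
        reports.append(evaluate(model, te, cfg, preprocessing, group_key=f"fold{i}"))
    return reports
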