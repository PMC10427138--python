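"""Segmentation losses and evaluation metrics.

IoU (intersection over union) is the evaluation metric: overlap of a
predicted and a ground-truth glottis mask divided by their union, 1 for a
perfect prediction.  The soft Dice loss is the training objective, and the
knowledge-distillation loss blends the Dice loss against the ground truth
with the Dice loss against a teacher model's soft prediction, weighted by
``alpha`` (alpha = 1 ignores the teacher entirely).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DICE_EPS",
    "iou",
    "dice_loss",
    "dice_loss_grad",
    "fkd_loss",
    "fkd_loss_grad",
    "mean_iou",
    "delta_miou",
    "EvaluationReport",
]

DICE_EPS = 1e-7


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError(f"{name} must be strictly binary")
    return mask


def iou(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Intersection over union of two binary masks; both-empty counts as 1.

    A correctly predicted all-background frame (closed glottis) is a perfect
    prediction, hence the both-empty convention.
    """
    pred_mask = _as_binary(pred_mask, "pred_mask")
    true_mask = _as_binary(true_mask, "true_mask")
    if pred_mask.shape != true_mask.shape:
        raise ValueError(f"shape mismatch: {pred_mask.shape} vs {true_mask.shape}")
    inter = np.count_nonzero(pred_mask & true_mask)
    union = np.count_nonzero(pred_mask | true_mask)
    if union == 0:
        return 1.0
    return inter / union


def dice_loss(pred_prob: np.ndarray, true_mask: np.ndarray) -> float:
    """Soft Dice loss: 1 - (2 Σ p·t + ε) / (Σ p + Σ t + ε).

    `pred_prob` is the network's probability map (no binarization), so the
    loss is differentiable; `true_mask` may itself be soft when it is a
    teacher model's prediction.
    """
    p = np.asarray(pred_prob, dtype=np.float64)
    t = np.asarray(true_mask, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("pred_prob must lie in [0, 1]")
    num = 2.0 * float((p * t).sum()) + DICE_EPS
    den = float(p.sum()) + float(t.sum()) + DICE_EPS
    return 1.0 - num / den


def dice_loss_grad(pred_prob: np.ndarray, true_mask: np.ndarray) -> np.ndarray:
    """d(dice_loss)/d(pred_prob), same shape as the prediction."""
    p = np.asarray(pred_prob, dtype=np.float64)
    t = np.asarray(true_mask, dtype=np.float64)
    num = 2.0 * float((p * t).sum()) + DICE_EPS
    den = float(p.sum()) + float(t.sum()) + DICE_EPS
    # quotient rule on -num/den
    return (num / den**2 - 2.0 * t / den).astype(np.float64)


def fkd_loss(
    student_prob: np.ndarray,
    true_mask: np.ndarray,
    teacher_prob: np.ndarray,
    alpha: float,
) -> float:
    """Knowledge-distillation loss: α·Dice(student, truth) + (1−α)·Dice(student, teacher).

    Larger alpha means less teacher influence; alpha = 1 reduces exactly to
    plain finetuning on the ground truth.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return alpha * dice_loss(student_prob, true_mask) + (1.0 - alpha) * dice_loss(
        student_prob, teacher_prob
    )


def fkd_loss_grad(
    student_prob: np.ndarray,
    true_mask: np.ndarray,
    teacher_prob: np.ndarray,
    alpha: float,
) -> np.ndarray:
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    g = alpha * dice_loss_grad(student_prob, true_mask)
    if alpha < 1.0:
        g = g + (1.0 - alpha) * dice_loss_grad(student_prob, teacher_prob)
    return g


def mean_iou(per_frame_iou: list[float] | np.ndarray) -> tuple[float, float]:
    """Mean and population SD of per-frame IoU values."""
    vals = np.asarray(per_frame_iou, dtype=np.float64)
    if vals.size == 0:
        raise ValueError("mean_iou of an empty frame list")
    return float(vals.mean()), float(vals.std())


def delta_miou(miou: float, baseline_miou: float) -> float:
    """mIoU difference vs a baseline, in percentage points (2-decimal rounding)."""
    return round((miou - baseline_miou) * 100.0, 2)


@dataclass
class EvaluationReport:
    """Per-frame IoU plus the summary statistics the benchmark tables report."""

    per_frame_iou: list[float]
    group_key: str = "all"
    baseline_miou: float | None = None
    miou: float = field(init=False)
    miou_sd: float = field(init=False)
    delta_miou_pp: float | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        self.miou, self.miou_sd = mean_iou(self.per_frame_iou)
        if self.baseline_miou is not None:
            self.delta_miou_pp = delta_miou(self.miou, self.baseline_miou)

    @property
    def n_frames(self) -> int:
        return len(self.per_frame_iou)

    def summary(self) -> dict:
        out = {
            "group": self.group_key,
            "n_frames": self.n_frames,
            "miou": round(self.miou, 4),
            "miou_sd": round(self.miou_sd, 4),
        }
        if self.delta_miou_pp is not None:
            out["delta_miou_pp"] = self.delta_miou_pp
        return out
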