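"""Training objective and evaluation metrics.

The training objective combines pixel-wise cross-entropy, region-level Dice
loss on the foreground softmax probability, and a weighted auxiliary
cross-entropy on the deep-supervision head::

    L_total = L_ce + L_dice + lambda_aux * L_aux

Dice is batch-pooled with smoothing ``eps = 1`` for stability on empty
masks.  Evaluation metrics (Dice, IoU, pixel accuracy, recall/sensitivity,
specificity, precision) are computed from a pooled confusion matrix per
image pair; dataset-level reports average per-image metrics by default, with
a pooled variant that satisfies the identity ``iou = dice / (2 - dice)``
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import Tensor


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def log_softmax(logits: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable log-softmax along ``axis``."""
    logits = nn.as_tensor(logits)
    shift = Tensor(logits.data.max(axis=axis, keepdims=True))  # constant
    z = logits - shift
    lse = nn.log(nn.tsum(nn.exp(z), axis=axis, keepdims=True))
    return z - lse


def cross_entropy(logits: Tensor, gt: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy of (B, K, H, W) logits against an
    integer mask (B, H, W) with values in {0..K-1}."""
    logits = nn.as_tensor(logits)
    b, k, h, w = logits.shape
    if gt.shape != (b, h, w):
        raise ValueError(f"mask shape {gt.shape} does not match logits {logits.shape}")
    onehot = np.zeros((b, k, h, w), dtype=logits.data.dtype)
    np.put_along_axis(onehot, gt.reshape(b, 1, h, w).astype(np.int64), 1.0, axis=1)
    return -nn.tmean(nn.tsum(log_softmax(logits) * Tensor(onehot), axis=1))


def dice_loss(probs, gt, eps: float = 1.0):
    """Soft Dice loss ``1 - (2 sum(p g) + eps) / (sum p + sum g + eps)``.

    ``probs`` is the foreground-probability map in [0, 1] (Tensor or array);
    ``gt`` is a binary mask of the same shape.  Sums pool over batch and
    space.  Returns a scalar :class:`Tensor`.
    """
    probs = nn.as_tensor(probs)
    tol = 1e-5  # tolerate float32 softmax round-off
    if probs.data.min() < -tol or probs.data.max() > 1 + tol:
        raise ValueError("probabilities must lie in [0, 1]")
    gt = np.asarray(gt)
    if gt.shape != probs.shape:
        raise ValueError(f"mask shape {gt.shape} does not match probs {probs.shape}")
    if not np.isin(gt, (0, 1)).all():
        raise ValueError("ground truth must be binary")
    g = Tensor(gt.astype(probs.data.dtype))
    inter = nn.tsum(probs * g)
    denom = nn.tsum(probs) + nn.tsum(g)
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


@dataclass
class LossBundle:
    """Scalar components of the training objective.

    ``total == ce + dice + lambda_aux * aux`` exactly; ``tensor`` carries the
    differentiable objective actually optimised (which may omit components
    under ablated loss configurations).
    """

    total: float
    ce: float
    dice: float
    aux: float
    lambda_aux: float
    tensor: Tensor = None

    def to_dict(self):
        d = asdict(self)
        d.pop("tensor")
        return d


def total_loss(seg_logits: Tensor, aux_logits, gt: np.ndarray,
               lambda_aux: float, loss_config: str = "ce+dice+aux") -> LossBundle:
    """Evaluate the combined objective on one batch.

    ``gt`` is a binary mask (B, H, W).  ``aux_logits`` may be None (the
    auxiliary term is then zero).  ``loss_config`` selects which components
    enter the differentiable objective ("ce", "ce+dice", "ce+dice+aux");
    the reported scalars always cover all components present.
    """
    gt = np.asarray(gt)
    ce = cross_entropy(seg_logits, gt)
    probs = nn.exp(log_softmax(seg_logits))  # (B,K,H,W)
    k = seg_logits.shape[1]
    sel = (np.arange(k) == 1).reshape(1, k, 1, 1).astype(seg_logits.data.dtype)
    fg = nn.tsum(probs * Tensor(sel), axis=1)  # foreground channel
    dice = dice_loss(fg, gt)
    if aux_logits is not None:
        if aux_logits.shape[2:] != gt.shape[1:]:
            raise ValueError(
                f"auxiliary logits {aux_logits.shape} do not match mask {gt.shape}")
        aux = cross_entropy(aux_logits, gt)
    else:
        aux = Tensor(np.zeros((), dtype=seg_logits.data.dtype))
    objective = ce
    if loss_config in ("ce+dice", "ce+dice+aux"):
        objective = objective + dice
    if loss_config == "ce+dice+aux" and aux_logits is not None:
        objective = objective + lambda_aux * aux
    ce_v, dice_v, aux_v = ce.item(), dice.item(), aux.item()
    return LossBundle(total=ce_v + dice_v + lambda_aux * aux_v,
                      ce=ce_v, dice=dice_v, aux=aux_v,
                      lambda_aux=lambda_aux, tensor=objective)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Pixel-level segmentation metrics, each in [0, 1]."""

    dice: float
    iou: float
    accuracy: float
    recall: float
    specificity: float
    precision: float

    def to_dict(self):
        return asdict(self)

    def to_percent_dict(self):
        return {k: 100.0 * v for k, v in asdict(self).items()}


def confusion_counts(pred, gt):
    """Pooled TP/FP/FN/TN of two binary masks."""
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    for name, m in (("prediction", pred), ("ground truth", gt)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary")
    p = pred.astype(bool)
    g = gt.astype(bool)
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return tp, fp, fn, tn


def _ratio(num, den, both_empty):
    """``num/den``; a 0/0 ratio reports 1 when both sides are empty, else 0."""
    if den > 0:
        return num / den
    return 1.0 if both_empty else 0.0


def metrics_from_counts(tp, fp, fn, tn) -> MetricsReport:
    n = tp + fp + fn + tn
    return MetricsReport(
        dice=_ratio(2 * tp, 2 * tp + fp + fn, True),
        iou=_ratio(tp, tp + fp + fn, True),
        accuracy=_ratio(tp + tn, n, True),
        recall=_ratio(tp, tp + fn, fp == 0),        # gt empty: 1 iff pred empty
        specificity=_ratio(tn, tn + fp, fn == 0),   # gt all-fg: 1 iff pred all-fg
        precision=_ratio(tp, tp + fp, fn == 0),     # pred empty: 1 iff gt empty
    )


def compute_metrics(pred_mask, gt_mask) -> MetricsReport:
    """Metrics of one prediction/ground-truth pair from pooled counts."""
    return metrics_from_counts(*confusion_counts(pred_mask, gt_mask))


def aggregate_metrics(pairs, reduction: str = "per_image") -> MetricsReport:
    """Dataset-level metrics over an iterable of (pred, gt) pairs.

    ``per_image`` (default) averages the per-pair metrics; ``pooled`` sums
    the confusion counts first (this variant satisfies
    ``iou == dice / (2 - dice)`` exactly).
    """
    if reduction == "pooled":
        tot = np.zeros(4, dtype=np.int64)
        for pred, gt in pairs:
            tot += confusion_counts(pred, gt)
        return metrics_from_counts(*tot)
    if reduction != "per_image":
        raise ValueError(f"unknown reduction {reduction!r}")
    reports = [compute_metrics(p, g).to_dict() for p, g in pairs]
    if not reports:
        raise ValueError("no pairs to aggregate")
    return MetricsReport(**{k: float(np.mean([r[k] for r in reports]))
                            for k in reports[0]})
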