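"""Training objective and metric suite, against hand-evaluated cases and
property-based checks of the Dice/IoU identity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcceunet import nn
from dcceunet.losses import (aggregate_metrics, compute_metrics, cross_entropy,
                             dice_loss, log_softmax, metrics_from_counts,
                             total_loss)


def test_dice_loss_hand_cases():
    # perfect overlap, nonempty: exactly zero
    g = np.array([[1.0, 1.0], [0.0, 1.0]])
    assert dice_loss(nn.Tensor(g), g).item() == pytest.approx(0.0, abs=1e-12)
    # the printed 2x2 case: p=[1,1,0,0], g=[1,0,0,0], eps=1 -> 1 - 3/4
    p = np.array([[1.0, 1.0], [0.0, 0.0]])
    g = np.array([[1.0, 0.0], [0.0, 0.0]])
    assert dice_loss(nn.Tensor(p), g).item() == pytest.approx(0.25)
    # fully disjoint half-foreground image: close to 1
    g = np.zeros((10, 10))
    g[:5] = 1
    loss = dice_loss(nn.Tensor(1 - g), g).item()
    assert loss == pytest.approx(1 - 1 / (100 + 1))
    with pytest.raises(ValueError):
        dice_loss(nn.Tensor(np.array([1.5])), np.array([1.0]))
    with pytest.raises(ValueError):
        dice_loss(nn.Tensor(np.array([0.5])), np.array([0.7]))


def test_cross_entropy_matches_per_pixel_oracle(rng):
    logits = rng.normal(size=(1, 2, 4, 4))
    gt = (rng.random((1, 4, 4)) > 0.5).astype(np.int64)
    ce = cross_entropy(nn.Tensor(logits), gt).item()
    # scripted per-pixel oracle
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    p = e / e.sum(axis=1, keepdims=True)
    ref = -np.mean([np.log(p[0, gt[0, i, j], i, j])
                    for i in range(4) for j in range(4)])
    assert ce == pytest.approx(ref, rel=1e-9)


def test_total_loss_bundle_invariant_and_oracle(rng):
    seg = nn.Tensor(rng.normal(size=(1, 2, 4, 4)))
    aux = nn.Tensor(rng.normal(size=(1, 2, 4, 4)))
    gt = (rng.random((1, 4, 4)) > 0.5).astype(np.int64)
    bundle = total_loss(seg, aux, gt, lambda_aux=0.4)
    assert bundle.total == pytest.approx(
        bundle.ce + bundle.dice + 0.4 * bundle.aux, abs=1e-12)
    # components recomputed independently
    ce_ref = cross_entropy(seg, gt).item()
    probs = np.exp(log_softmax(seg).data)[:, 1]
    dice_ref = dice_loss(nn.Tensor(probs), gt.astype(float)).item()
    aux_ref = cross_entropy(aux, gt).item()
    assert bundle.ce == pytest.approx(ce_ref, rel=1e-7)
    assert bundle.dice == pytest.approx(dice_ref, rel=1e-6)
    assert bundle.aux == pytest.approx(aux_ref, rel=1e-7)


def test_total_loss_weight_zero_and_missing_aux(rng):
    seg = nn.Tensor(rng.normal(size=(1, 2, 4, 4)))
    aux = nn.Tensor(rng.normal(size=(1, 2, 4, 4)))
    gt = (rng.random((1, 4, 4)) > 0.5).astype(np.int64)
    b0 = total_loss(seg, aux, gt, lambda_aux=0.0)
    assert b0.total == pytest.approx(b0.ce + b0.dice)
    none = total_loss(seg, None, gt, lambda_aux=0.4)
    assert none.aux == 0.0
    with pytest.raises(ValueError):
        total_loss(seg, nn.Tensor(rng.normal(size=(1, 2, 8, 8))), gt, 0.4)


def test_confident_logits_drive_ce_to_zero(rng):
    gt = (rng.random((1, 4, 4)) > 0.5).astype(np.int64)
    logits = np.zeros((1, 2, 4, 4))
    np.put_along_axis(logits, gt[:, None], 50.0, axis=1)
    bundle = total_loss(nn.Tensor(logits), None, gt, 0.4)
    assert bundle.ce == pytest.approx(0.0, abs=1e-6)
    # only the epsilon-smoothing residual of the Dice term remains
    s = gt.sum()
    assert bundle.dice == pytest.approx(1 - (2 * s + 1) / (2 * s + 1), abs=1e-6)


def test_metrics_toy_confusion():
    """TP=FP=FN=TN=1 gives dice 1/2, iou 1/3, and 1/2 for the others."""
    rep = metrics_from_counts(1, 1, 1, 1)
    assert rep.dice == pytest.approx(0.5)
    assert rep.iou == pytest.approx(1 / 3)
    assert rep.accuracy == pytest.approx(0.5)
    assert rep.recall == pytest.approx(0.5)
    assert rep.specificity == pytest.approx(0.5)
    assert rep.precision == pytest.approx(0.5)
    # realised by an explicit 4-pixel pair
    pred = np.array([[1, 1], [0, 0]])
    gt = np.array([[1, 0], [1, 0]])
    assert compute_metrics(pred, gt) == rep


def test_metrics_identity_and_empty_conventions():
    pred = np.array([[1, 0], [0, 1]])
    assert compute_metrics(pred, pred) == metrics_from_counts(2, 0, 0, 2)
    assert all(v == 1.0 for v in compute_metrics(pred, pred).to_dict().values())
    empty = np.zeros((3, 3), dtype=int)
    rep = compute_metrics(empty, empty)
    assert rep.dice == rep.iou == rep.recall == rep.precision == 1.0
    # empty prediction on a lesion image: recall 0
    gt = np.ones((3, 3), dtype=int)
    assert compute_metrics(empty, gt).recall == 0.0
    with pytest.raises(ValueError):
        compute_metrics(np.array([[0.5]]), np.array([[1]]))


@settings(derandomize=True, max_examples=200)
@given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
       st.integers(0, 50))
def test_iou_dice_identity_on_pooled_counts(tp, fp, fn, tn):
    """iou == dice / (2 - dice) for every pooled confusion matrix."""
    rep = metrics_from_counts(tp, fp, fn, tn)
    assert abs(rep.iou - rep.dice / (2 - rep.dice)) < 1e-12


def test_dice_loss_complements_dice_metric_on_hard_masks(rng):
    """With eps -> 0, dice_loss on identical hard masks plus the Dice metric
    equals exactly one."""
    gt = (rng.random((6, 6)) > 0.4).astype(float)
    loss = dice_loss(nn.Tensor(gt), gt, eps=1e-12).item()
    metric = compute_metrics(gt.astype(int), gt.astype(int)).dice
    assert loss + metric == pytest.approx(1.0, abs=1e-9)


def test_aggregate_reductions(rng):
    pairs = [((rng.random((5, 5)) > 0.5).astype(int),
              (rng.random((5, 5)) > 0.5).astype(int)) for _ in range(4)]
    per_img = aggregate_metrics(pairs, "per_image")
    pooled = aggregate_metrics(pairs, "pooled")
    assert abs(pooled.iou - pooled.dice / (2 - pooled.dice)) < 1e-12
    for v in (*per_img.to_dict().values(), *pooled.to_dict().values()):
        assert 0.0 <= v <= 1.0
    with pytest.raises(ValueError):
        aggregate_metrics(pairs, "median")
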