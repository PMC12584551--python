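"""Data loading, splitting, training, evaluation and prediction.

The harness follows a fixed, fully seeded protocol: images and masks are
paired by filename stem (either an ``images/`` + ``masks/`` folder layout or
a flat folder with ``*_mask.png`` companions), split 8:1:1 by a seeded
shuffle, resized for the network, and optimised with SGD (momentum 0.9,
weight decay 5e-5) under a cosine-annealed learning rate starting at 0.01.
After every epoch the validation Dice is computed and the best-so-far
weights are checkpointed; evaluation runs in inference mode, resizes the
predicted mask back to the native ground-truth resolution with
nearest-neighbour interpolation, and averages per-image metrics.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as sk_resize

from . import nn
from .config import ModelConfig, TrainConfig
from .losses import aggregate_metrics, total_loss, MetricsReport
from .network import DCCEUNet, build_model

MASK_THRESHOLD = 127  # mask PNGs are {0,255}; binarise at the midpoint


@dataclass
class Sample:
    """One image/mask pair; image in [0,1], mask binary, same shape."""

    stem: str
    image: np.ndarray
    mask: np.ndarray


# ---------------------------------------------------------------------------
# loading and splitting
# ---------------------------------------------------------------------------

def _discover_pairs(data_dir: Path) -> dict:
    """Map stem -> (image_path, mask_path) for both accepted layouts."""
    img_dir, mask_dir = data_dir / "images", data_dir / "masks"
    pairs = {}
    if img_dir.is_dir() and mask_dir.is_dir():
        imgs = {p.stem: p for p in sorted(img_dir.glob("*.png"))}
        masks = {p.stem: p for p in sorted(mask_dir.glob("*.png"))}
        missing = sorted(set(imgs) ^ set(masks))
        if missing:
            raise ValueError(f"unmatched image/mask stems: {missing}")
        pairs = {s: (imgs[s], masks[s]) for s in imgs}
    else:
        for p in sorted(data_dir.glob("*.png")):
            if p.stem.endswith("_mask"):
                continue
            m = p.with_name(p.stem + "_mask.png")
            if not m.exists():
                raise ValueError(f"no mask found for {p.name}")
            pairs[p.stem] = (p, m)
    if not pairs:
        raise ValueError(f"no image/mask pairs found under {data_dir}")
    return pairs


def load_sample(image_path, mask_path) -> Sample:
    """Load a PNG pair: image as grayscale in [0,1], mask binarised at 127."""
    img = np.asarray(Image.open(image_path).convert("L"), dtype=np.float32) / 255.0
    mask = np.asarray(Image.open(mask_path).convert("L")) > MASK_THRESHOLD
    if img.shape != mask.shape:
        raise ValueError(f"{Path(image_path).stem}: image {img.shape} vs mask {mask.shape}")
    return Sample(Path(image_path).stem, img, mask.astype(np.uint8))


def load_split(data_dir, ratios=(0.8, 0.1, 0.1), seed: int = 0):
    """Deterministically split the dataset into (train, val, test) lists.

    Sizes follow floor allocation for val/test with the remainder going to
    train; the shuffle is a seeded permutation of the sorted stems.
    """
    data_dir = Path(data_dir)
    pairs = _discover_pairs(data_dir)
    stems = sorted(pairs)
    order = np.random.default_rng(seed).permutation(len(stems))
    n = len(stems)
    n_val, n_test = int(n * ratios[1]), int(n * ratios[2])
    n_train = n - n_val - n_test
    shuffled = [stems[i] for i in order]
    out = []
    for lo, hi in ((0, n_train), (n_train, n_train + n_val), (n_train + n_val, n)):
        out.append([load_sample(*pairs[s]) for s in shuffled[lo:hi]])
    return tuple(out)


def _resize_image(img: np.ndarray, hw) -> np.ndarray:
    if img.shape == tuple(hw):
        return img.astype(np.float32)
    return sk_resize(img, hw, order=1, preserve_range=True,
                     anti_aliasing=False).astype(np.float32)


def _resize_mask(mask: np.ndarray, hw) -> np.ndarray:
    if mask.shape == tuple(hw):
        return mask.astype(np.uint8)
    return sk_resize(mask.astype(np.uint8), hw, order=0, preserve_range=True,
                     anti_aliasing=False).astype(np.uint8)


def _as_batches(samples, hw, batch_size, order=None):
    idx = np.arange(len(samples)) if order is None else order
    for lo in range(0, len(idx), batch_size):
        chunk = [samples[i] for i in idx[lo:lo + batch_size]]
        x = np.stack([_resize_image(s.image, hw) for s in chunk])[:, None]
        y = np.stack([_resize_mask(s.mask, hw) for s in chunk])
        yield x.astype(np.float32), y.astype(np.int64), chunk


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(ckpt: dict, path):
    """Persist a checkpoint dict (weights + configs) to an .npz file."""
    arrays = {f"state/{k}": v for k, v in ckpt["state"].items()}
    meta = {k: v for k, v in ckpt.items() if k != "state"}
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path):
    """Load a checkpoint; returns ``(model, meta)`` with the model in eval mode."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k[len("state/"):]: z[k] for k in z.files if k.startswith("state/")}
    model = build_model(ModelConfig.from_dict(meta["model_config"]))
    model.load_state_dict(state)
    return model.eval(), meta


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _val_dice(model: DCCEUNet, samples, hw, batch_size) -> float:
    model.eval()
    pairs = []
    with nn.no_grad():
        for x, _, chunk in _as_batches(samples, hw, batch_size):
            seg, _ = model(x)
            pred = seg.data.argmax(axis=1).astype(np.uint8)
            for p, s in zip(pred, chunk):
                pairs.append((_resize_mask(p, s.mask.shape), s.mask))
    model.train()
    return aggregate_metrics(pairs).dice


def train(model_config: ModelConfig, train_config: TrainConfig, data_dir,
          out_dir=None, log=None):
    """Train a model on a directory of image/mask PNGs.

    Returns ``(checkpoint, history)``: the checkpoint dict holds the weights
    with the highest validation Dice (plus both configs and the best epoch);
    the history lists per-epoch loss components, learning rate and
    validation Dice.  Raises on non-finite loss.
    """
    tc, mc = train_config, model_config
    tr, va, _ = load_split(data_dir, tc.split_ratios, tc.seed)
    if not tr or not va:
        raise ValueError("training and validation splits must be nonempty")
    model = build_model(mc)
    opt = nn.SGD(model.parameters(), lr=tc.lr0, momentum=tc.momentum,
                 weight_decay=tc.weight_decay)
    rng = np.random.default_rng(tc.seed + 1)
    history, best = [], None
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    for epoch in range(tc.epochs):
        opt.lr = nn.cosine_lr(tc.lr0, epoch, tc.epochs)
        order = rng.permutation(len(tr))
        sums = np.zeros(4)
        n_batches = 0
        for x, y, _ in _as_batches(tr, tc.resize, tc.batch_size, order):
            seg, aux = model(x)
            bundle = total_loss(seg, aux, y, mc.lambda_aux, tc.loss_config)
            if not np.isfinite(bundle.total):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            bundle.tensor.backward()
            opt.step()
            sums += (bundle.total, bundle.ce, bundle.dice, bundle.aux)
            n_batches += 1
        val_dice = _val_dice(model, va, tc.resize, tc.batch_size)
        rec = {
            "epoch": epoch, "lr": opt.lr,
            "loss_total": sums[0] / n_batches, "loss_ce": sums[1] / n_batches,
            "loss_dice": sums[2] / n_batches, "loss_aux": sums[3] / n_batches,
            "val_dice": val_dice,
        }
        if best is None or val_dice > best["best_val_dice"]:
            best = {
                "state": copy.deepcopy(model.state_dict()),
                "model_config": mc.to_dict(), "train_config": tc.to_dict(),
                "best_val_dice": val_dice, "best_epoch": epoch,
            }
        rec["best_val_dice"] = best["best_val_dice"]
        history.append(rec)
        if log:
            log(rec)
        if out:
            with open(out / "history.jsonl", "a") as fh:
                fh.write(json.dumps(rec) + "\n")
    if out:
        save_checkpoint(best, out / "best.npz")
        best["path"] = str(out / "best.npz")
    return best, history


# ---------------------------------------------------------------------------
# evaluation and prediction
# ---------------------------------------------------------------------------

def predict_mask(model: DCCEUNet, image: np.ndarray, resize_hw) -> np.ndarray:
    """Segment one [0,1] grayscale image; returns a binary mask at the
    image's native resolution (argmax decision, nearest-neighbour resize)."""
    x = _resize_image(image, resize_hw)[None, None]
    model.eval()
    with nn.no_grad():
        seg, _ = model(x)
    pred = seg.data.argmax(axis=1)[0].astype(np.uint8)
    return _resize_mask(pred, image.shape)


def evaluate(model: DCCEUNet, samples, resize_hw, batch_size: int = 8,
             reduction: str = "per_image") -> MetricsReport:
    """Evaluate on a list of samples, scoring at native mask resolution."""
    if not samples:
        raise ValueError("empty evaluation split")
    model.eval()
    pairs = []
    with nn.no_grad():
        for x, _, chunk in _as_batches(samples, resize_hw, batch_size):
            seg, _ = model(x)
            pred = seg.data.argmax(axis=1).astype(np.uint8)
            for p, s in zip(pred, chunk):
                pairs.append((_resize_mask(p, s.mask.shape), s.mask))
    return aggregate_metrics(pairs, reduction)


def predict(checkpoint_path, image_path, out_path) -> np.ndarray:
    """Segment one image file and write the {0,255} mask PNG."""
    model, meta = load_checkpoint(checkpoint_path)
    img = np.asarray(Image.open(image_path).convert("L"), dtype=np.float32) / 255.0
    hw = tuple(meta["train_config"]["resize"])
    mask = predict_mask(model, img, hw)
    Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(out_path, format="PNG")
    return mask
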