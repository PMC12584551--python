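"""Model and training configuration.

The architecture hyperparameters that the printed complexity budget pins down
(channel ladder, attention reductions, context-grid size, strip kernel) live
in :class:`ModelConfig`; their defaults are the calibrated values that
reproduce the parameter/MAC ladder of the four ablation variants at 224x224
(see ``scripts/calibrate_budget.py`` for the scripted calibration).
Training-protocol settings live in :class:`TrainConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

VARIANTS = ("unet", "bda", "bda_cag", "full")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Parameters
    ----------
    in_channels
        Input image channels; ultrasound is grayscale, so 1.
    num_classes
        Output channels of the softmax head (background/lesion -> 2).
    base_channels
        Encoder widths [C0..C4]: stem, four encoder stages.  Calibrated so
        the four ablation variants reproduce the published complexity ladder.
    dilation_rates
        Dilation rates of the four parallel context branches at the
        bottleneck.
    masg_channels
        Embedding width C' of the bottleneck attention block (also the width
        handed to the decoder when the block is enabled).
    attention_reduction
        Channel reduction r of the bottleneck attention sub-network
        (2C' -> C'/r -> C').
    sava_reduction
        Channel reduction of the variance-gate bottleneck inside SAVA.
    cag_kernel
        Odd strip length k of the horizontal 1xk / vertical kx1 depthwise
        convolutions.
    cag_expansion
        Channel expansion of the context embedding (C -> expansion * C).
    cag_grid
        Side length of the pooled context grid the strips run on.
    lambda_aux
        Weight of the auxiliary deep-supervision loss.
    bda / cag / masg
        Ablation flags; all False gives the plain U-Net baseline.
    input_size
        (H, W) used for the complexity audit; must be divisible by 16.
    seed
        Seed of the weight-initialisation RNG.
    """

    in_channels: int = 1
    num_classes: int = 2
    base_channels: tuple = (22, 66, 138, 218, 282)
    dilation_rates: tuple = (1, 6, 12, 18)
    masg_channels: int = 340
    attention_reduction: int = 6
    sava_reduction: int = 4
    cag_kernel: int = 9
    cag_expansion: int = 15
    cag_grid: int = 13
    lambda_aux: float = 0.4
    bda: bool = True
    cag: bool = True
    masg: bool = True
    input_size: tuple = (224, 224)
    seed: int = 0

    def __post_init__(self):
        self.base_channels = tuple(int(c) for c in self.base_channels)
        self.dilation_rates = tuple(int(d) for d in self.dilation_rates)
        self.input_size = tuple(int(s) for s in self.input_size)
        self.validate()

    def validate(self):
        if len(self.base_channels) != 5:
            raise ValueError("base_channels must list five widths [C0..C4]")
        if any(a >= b for a, b in zip(self.base_channels, self.base_channels[1:])):
            raise ValueError("base_channels must be strictly increasing")
        if self.cag_kernel % 2 == 0:
            raise ValueError(f"cag_kernel must be odd, got {self.cag_kernel}")
        if self.lambda_aux < 0:
            raise ValueError("lambda_aux must be nonnegative")
        if self.masg_channels % 4:
            raise ValueError("masg_channels must be divisible by 4")
        h, w = self.input_size
        if h % 16 or w % 16:
            raise ValueError(f"input_size must be divisible by 16, got {h}x{w}")
        if min(self.in_channels, self.num_classes) < 1:
            raise ValueError("in_channels and num_classes must be >= 1")

    # -- variants -----------------------------------------------------------
    def with_variant(self, name: str) -> "ModelConfig":
        """Return a copy with the ablation flags of a named variant."""
        flags = {
            "unet": dict(bda=False, cag=False, masg=False),
            "bda": dict(bda=True, cag=False, masg=False),
            "bda_cag": dict(bda=True, cag=True, masg=False),
            "full": dict(bda=True, cag=True, masg=True),
        }
        if name not in flags:
            raise ValueError(f"unknown variant {name!r}; choose from {VARIANTS}")
        d = asdict(self)
        d.update(flags[name])
        return ModelConfig(**d)

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Small configuration for desk-scale experiments (base width 16)."""
        d = dict(
            base_channels=(16, 32, 64, 128, 256),
            masg_channels=256,
            attention_reduction=4,
            sava_reduction=4,
            cag_expansion=2,
            cag_grid=8,
            cag_kernel=5,
            input_size=(64, 64),
        )
        d.update(overrides)
        return cls(**d)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        model = raw.get("model", raw)
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in model.items() if k in known})


@dataclass
class TrainConfig:
    """Optimisation protocol: SGD with momentum, cosine-annealed learning
    rate, best-validation-Dice checkpointing."""

    epochs: int = 100
    batch_size: int = 8
    lr0: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 5e-5
    resize: tuple = (224, 224)
    split_ratios: tuple = (0.8, 0.1, 0.1)
    seed: int = 0
    loss_config: str = "ce+dice+aux"  # or "ce" / "ce+dice"

    def __post_init__(self):
        self.resize = tuple(int(s) for s in self.resize)
        self.split_ratios = tuple(float(r) for r in self.split_ratios)
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split_ratios must sum to 1")
        if min(self.epochs, self.batch_size) < 1 or self.lr0 <= 0:
            raise ValueError("epochs, batch_size and lr0 must be positive")
        if self.loss_config not in ("ce", "ce+dice", "ce+dice+aux"):
            raise ValueError(f"unknown loss_config {self.loss_config!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        train = raw.get("train", raw)
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in train.items() if k in known})
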