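"""Network assembly: encoder-decoder backbone with optional attention modules,
plus the parameter/MAC complexity audit.

The backbone is a U-Net: a stem double convolution, four max-pool encoder
stages, and four decoder stages (bilinear 2x upsample + 1x1 projection,
skip concatenation, double convolution).  Three optional modules extend it:

* a bottleneck block building contrastive attention from multi-source
  references and aggregating dilated multi-scale context, with an auxiliary
  deep-supervision head (``masg`` flag),
* difference-aware skip fusion at every stage (``bda`` flag),
* strip-convolution context gating after every decoder stage (``cag`` flag).

With all flags off the model is a plain U-Net baseline.  The complexity
audit counts trainable parameters exactly and multiply-accumulate
operations per layer from the traced spatial sizes (one MAC per
multiply-add in convolutions and affine normalisation layers; pooling,
interpolation and activations are free).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Module, Tensor
from .config import ModelConfig
from .masg import ConvBNReLU, MasgBlock
from .bda import BdaBlock
from .cag import CagBlock, SegHead


class DoubleConv(Module):
    """Two 3x3 Conv-BN-ReLU layers (the U-Net workhorse block)."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        self.c1 = ConvBNReLU(cin, cout, 3, rng)
        self.c2 = ConvBNReLU(cout, cout, 3, rng)

    def forward(self, x):
        return self.c2(self.c1(x))

    def complexity(self, h, w):
        return self.c1.complexity(h, w) + self.c2.complexity(h, w)


class DecoderStage(Module):
    """Bilinear 2x upsample + 1x1 projection, skip fusion, double conv,
    optional context gating."""

    def __init__(self, name: str, c_in: int, c_skip: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.name = name
        self.proj = ConvBNReLU(c_in, c_skip, 1, rng)
        self.bda = BdaBlock(c_skip, cfg.sava_reduction, rng) if cfg.bda else None
        self.dconv = DoubleConv(2 * c_skip, c_skip, rng)
        self.cag = (CagBlock(c_skip, cfg.cag_kernel, cfg.cag_expansion,
                             cfg.cag_grid, rng) if cfg.cag else None)

    def align(self, f_dec: Tensor, target_hw) -> Tensor:
        """Upsample the incoming decoder feature and project it to the skip
        width; with BDA enabled this projection is also the BDA alignment."""
        return self.proj(nn.bilinear_resize(f_dec, target_hw))

    def forward(self, f_dec: Tensor, f_skip: Tensor) -> Tensor:
        aligned = self.align(f_dec, f_skip.shape[2:])
        if aligned.shape != f_skip.shape:
            raise ValueError(
                f"decoder stage {self.name}: aligned feature {aligned.shape} "
                f"does not match skip feature {f_skip.shape}")
        skip = self.bda(f_skip, aligned) if self.bda is not None else f_skip
        x = self.dconv(nn.concat([aligned, skip], axis=1))
        if self.cag is not None:
            x = self.cag(x)
        return x

    def complexity(self, h, w):
        m = self.proj.complexity(h, w)
        if self.bda is not None:
            m += self.bda.complexity(h, w)
        m += self.dconv.complexity(h, w)
        if self.cag is not None:
            m += self.cag.complexity(h, w)
        return m


class DCCEUNet(Module):
    """Difference and context-aware contrast-enhanced U-Net."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        C = cfg.base_channels
        self.stem = DoubleConv(cfg.in_channels, C[0], rng)
        self.encoders = [DoubleConv(C[i], C[i + 1], rng) for i in range(4)]
        bottleneck_c = C[4]
        if cfg.masg:
            self.masg = MasgBlock(C[4], C[3], C[0], cfg.masg_channels,
                                  cfg.attention_reduction, cfg.dilation_rates,
                                  cfg.num_classes, rng)
            bottleneck_c = cfg.masg_channels
        else:
            self.masg = None
        self.decoders = []
        c_in = bottleneck_c
        for lvl in (3, 2, 1, 0):
            self.decoders.append(DecoderStage(f"dec{lvl}", c_in, C[lvl], cfg, rng))
            c_in = C[lvl]
        self.head = SegHead(C[0], cfg.num_classes, rng)

    def forward(self, x):
        """Run the network; returns ``(seg_logits, aux_logits_or_None)``."""
        x = nn.as_tensor(x)
        b, c, h, w = x.shape
        if c != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} input channels, got {c}")
        if h % 16 or w % 16:
            raise ValueError(f"input spatial size must be divisible by 16, got {h}x{w}")
        f0 = self.stem(x)
        feats = [f0]
        f = f0
        for enc in self.encoders:
            f = enc(nn.maxpool2d(f))
            feats.append(f)
        aux = None
        if self.masg is not None:
            f, aux = self.masg(feats[4], feats[3], feats[0], (h, w))
        for lvl, dec in zip((3, 2, 1, 0), self.decoders):
            f = dec(f, feats[lvl])
        return self.head(f), aux

    def complexity(self, h, w):
        """Total MACs of one forward pass at input size ``h`` x ``w``."""
        hs = [h, h // 2, h // 4, h // 8, h // 16]
        ws = [w, w // 2, w // 4, w // 8, w // 16]
        m = self.stem.complexity(hs[0], ws[0])
        for i, enc in enumerate(self.encoders):
            m += enc.complexity(hs[i + 1], ws[i + 1])
        if self.masg is not None:
            m += self.masg.complexity(hs[4], ws[4])
        for lvl, dec in zip((3, 2, 1, 0), self.decoders):
            m += dec.complexity(hs[lvl], ws[lvl])
        m += self.head.complexity(hs[0], ws[0])
        return m


@dataclass
class ComplexityReport:
    """Trainable parameters (millions) and forward MACs (billions)."""

    params_millions: float
    gmacs: float


def build_model(config: ModelConfig) -> DCCEUNet:
    """Build a seeded network from a configuration."""
    return DCCEUNet(config)


def count_complexity(model: DCCEUNet, input_size=None) -> ComplexityReport:
    """Audit model complexity at ``input_size`` (defaults to the config's)."""
    h, w = input_size or model.cfg.input_size
    if h % 16 or w % 16:
        raise ValueError(f"audit input size must be divisible by 16, got {h}x{w}")
    return ComplexityReport(
        params_millions=model.num_parameters() / 1e6,
        gmacs=model.complexity(h, w) / 1e9,
    )
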