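"""Bidirectional difference-aware attention (skip-connection module).

BDA replaces the plain copy of an encoder feature across a skip connection
with a boundary-sensitive fusion of the encoder feature and the aligned
decoder feature:

1. the raw decoder feature is aligned to the encoder stage (bilinear
   upsampling + 1x1 projection; the decoder stage's projection serves as the
   alignment, so there is a single projection per stage),
2. an embedding block (EmB) forms cross-stage difference features and
   applies residual attention weighting in both directions,
3. the two modulated features are differenced again and passed through a
   final spatial-variance-aware attention (SAVA) module.

The SAVA and the gate convolution inside the EmB are shared by the two
pathways: with shared weights the module is exactly null for identical
inputs (identical encoder/decoder features yield ``F_bda == 0``), which is
the behaviour the difference construction is meant to have.  The closing
SAVA has its own weights.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Module, Conv2d, Tensor
from .masg import residual_gate


class Sava(Module):
    """Spatial-variance-aware attention.

    A channel gate is derived from the per-channel *population* variance over
    spatial locations (a C-vector per sample), squeezed through a two-layer
    bottleneck with a sigmoid; a spatial gate is the sigmoid of a 7x7
    convolution over the concatenated channel-mean and channel-max maps.
    The input is modulated by both gates: ``F * w * s``.
    """

    def __init__(self, c: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(1, c // reduction)
        self.fc1 = Conv2d(c, hidden, 1, rng)
        self.fc2 = Conv2d(hidden, c, 1, rng)
        self.spatial = Conv2d(2, 1, 7, rng, padding=3)

    def forward(self, f: Tensor) -> Tensor:
        b, c, h, w = f.shape
        if h * w < 2:
            raise ValueError("SAVA needs at least two spatial locations")
        m = nn.tmean(f, axis=(2, 3), keepdims=True)
        fc = f - m
        var = nn.tmean(fc * fc, axis=(2, 3), keepdims=True)      # (B,C,1,1)
        wgate = nn.sigmoid(self.fc2(nn.relu(self.fc1(var))))
        smap = nn.concat([nn.tmean(f, axis=1, keepdims=True),
                          nn.amax(f, axis=1, keepdims=True)], axis=1)
        sgate = nn.sigmoid(self.spatial(smap))
        return f * wgate * sgate

    def complexity(self, h, w):
        # variance bottleneck acts on a 1x1 map; spatial conv on the full grid
        return self.fc1.macs(1, 1) + self.fc2.macs(1, 1) + self.spatial.macs(h, w)


class BdaBlock(Module):
    """Difference-aware fusion of one encoder/decoder feature pair.

    ``forward`` expects the decoder feature already aligned to the encoder
    stage (same channels and spatial size); in the network the decoder
    stage's upsample + 1x1 projection provides that alignment.
    """

    def __init__(self, c_enc: int, sava_reduction: int, rng: np.random.Generator):
        super().__init__()
        self.c_enc = c_enc
        from .nn import BatchNorm2d
        self.emb_sava = Sava(c_enc, sava_reduction, rng)   # shared by both pathways
        self.gate_conv = Conv2d(c_enc, c_enc, 1, rng, bias=False)  # shared gate
        self.gate_bn = BatchNorm2d(c_enc)
        self.final_sava = Sava(c_enc, sava_reduction, rng)

    def _gate(self, f_sub: Tensor) -> Tensor:
        return nn.sigmoid(self.gate_bn(self.gate_conv(f_sub)))

    def emb_block(self, f_enc: Tensor, f_dec: Tensor):
        """Cross-stage difference + residual weighting, both directions.

        Encoder pathway: ``F_sub = F_enc - SAVA(F_dec)``,
        ``F_mod_enc = F_enc + sigmoid(BN(conv(F_sub))) * F_enc``; the decoder
        pathway swaps the roles.  Returns ``(F_mod_enc, F_mod_dec)``.
        """
        if f_enc.shape != f_dec.shape:
            raise ValueError(
                f"EmB inputs must share shape, got {f_enc.shape} vs {f_dec.shape}")
        f_mod_enc = residual_gate(f_enc, self._gate(f_enc - self.emb_sava(f_dec)))
        f_mod_dec = residual_gate(f_dec, self._gate(f_dec - self.emb_sava(f_enc)))
        return f_mod_enc, f_mod_dec

    def forward(self, f_enc: Tensor, f_dec_aligned: Tensor) -> Tensor:
        """Return the fused skip feature ``F_bda`` at the encoder's shape."""
        if f_enc.shape[1] != self.c_enc:
            raise ValueError(
                f"BDA stage expects {self.c_enc} encoder channels, got {f_enc.shape[1]}")
        f_mod_enc, f_mod_dec = self.emb_block(f_enc, f_dec_aligned)
        return self.final_sava(f_mod_enc - f_mod_dec)

    def complexity(self, h, w):
        # shared modules run once per pathway, so their MACs count twice
        m = 2 * self.emb_sava.complexity(h, w)
        m += 2 * (self.gate_conv.macs(h, w) + self.gate_bn.macs(h, w))
        m += self.final_sava.complexity(h, w)
        return m
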