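"""Context-aware guidance (decoder-stage module) and the segmentation head.

CAG captures long-range axis-aligned context: the decoder feature is
average-pooled onto a small context grid and embedded by a 1x1 convolution;
depthwise 1xk (horizontal) and kx1 (vertical) strip convolutions then encode
row-wise and column-wise dependencies; their sum is turned into an attention
map by a 1x1 convolution + sigmoid, upsampled back to the stage resolution,
and used to gate the decoder feature residually::

    A_cag = upsample(sigmoid(conv(F_h + F_v)))
    F_cag = F_dec + A_cag * F_dec

The strips are channel-independent (depthwise); the surrounding 1x1
convolutions carry the cross-channel mixing.  Running them on the pooled
grid keeps the computational overhead small while the wide embedding keeps
the module expressive.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Module, Conv2d, BatchNorm2d, StripConv, Tensor
from .masg import residual_gate


class CagBlock(Module):
    """Dual-path horizontal/vertical context gating for one decoder stage."""

    def __init__(self, c: int, kernel: int, expansion: int, grid: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"strip kernel must be odd, got {kernel}")
        ce = expansion * c
        self.grid = grid
        self.embed_conv = Conv2d(c, ce, 1, rng, bias=False)
        self.embed_bn = BatchNorm2d(ce)
        self.strip_h = StripConv(ce, kernel, horizontal=True, rng=rng)
        self.strip_v = StripConv(ce, kernel, horizontal=False, rng=rng)
        self.att_conv = Conv2d(ce, c, 1, rng)

    def embed(self, f_dec: Tensor) -> Tensor:
        """Average-pool onto the context grid and embed with 1x1 conv."""
        pooled = nn.adaptive_avgpool(f_dec, self.grid)
        return nn.relu(self.embed_bn(self.embed_conv(pooled)))

    def cag_context(self, f_dec: Tensor):
        """Return the horizontal and vertical strip features ``(F_h, F_v)``
        on the context grid."""
        e = self.embed(f_dec)
        return self.strip_h(e), self.strip_v(e)

    def forward(self, f_dec: Tensor) -> Tensor:
        f_h, f_v = self.cag_context(f_dec)
        a_small = nn.sigmoid(self.att_conv(f_h + f_v))
        a = nn.bilinear_resize(a_small, f_dec.shape[2:])
        return residual_gate(f_dec, a)

    def complexity(self, h, w):
        g = min(self.grid, h), min(self.grid, w)
        m = self.embed_conv.macs(*g) + self.embed_bn.macs(*g)
        m += self.strip_h.macs(*g) + self.strip_v.macs(*g)
        m += self.att_conv.macs(*g)
        return m


class SegHead(Module):
    """Final prediction head: 3x3 conv + ReLU, then 1x1 conv to class logits."""

    def __init__(self, c: int, num_classes: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(c, c, 3, rng, padding=1)
        self.conv2 = Conv2d(c, num_classes, 1, rng)

    def forward(self, f: Tensor) -> Tensor:
        return self.conv2(nn.relu(self.conv1(f)))

    def complexity(self, h, w):
        return self.conv1.macs(h, w) + self.conv2.macs(h, w)
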