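"""Multi-source attention-guided semantic generation (bottleneck block).

The block contrasts the bottleneck feature with two reference features — the
stage-3 encoder feature as the foreground reference and the stem double-conv
feature as the background reference — to build a contrastive-difference
attention map, then aggregates multi-scale context with four parallel dilated
convolutions, and finally emits an auxiliary segmentation prediction for deep
supervision.

Pipeline (all at the bottleneck's spatial resolution)::

    F'_in, F'_fg, F'_bg = embed(F_enc4), embed(resize(F_enc3)), embed(resize(F_stem))
    F_diff = concat(F'_in - F'_fg, F'_in - F'_bg)            # 2C' channels
    A      = sigmoid(conv(relu(conv(F_diff))))   # 1x1 convs, 2C' -> C'/r -> C'
    F_att  = F'_in + A * F'_in
    F_dec0 = reduce(concat(F_att, dilated branches d={1,6,12,18}))
    F_aux  = upsample(head(F_dec0))                           # auxiliary logits
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Module, Conv2d, BatchNorm2d, Tensor


class ConvBNReLU(Module):
    def __init__(self, cin, cout, k, rng, dilation=1):
        super().__init__()
        pad = dilation * (k // 2)
        self.conv = Conv2d(cin, cout, k, rng, padding=pad, dilation=dilation, bias=False)
        self.bn = BatchNorm2d(cout)

    def forward(self, x):
        return nn.relu(self.bn(self.conv(x)))

    def complexity(self, h, w):
        return self.conv.macs(h, w) + self.bn.macs(h, w)


def embed_reference(block: ConvBNReLU, feature: Tensor, target_hw: tuple[int, int]) -> Tensor:
    """Bilinearly resize ``feature`` to ``target_hw``, then embed it with a
    1x1 conv + BN + ReLU.  The resize precedes the embedding."""
    if min(target_hw) < 1:
        raise ValueError(f"zero-sized embedding target {target_hw}")
    return block(nn.bilinear_resize(feature, target_hw))


def residual_gate(f: Tensor, a: Tensor) -> Tensor:
    """Residual attention fusion ``f + a * f`` (shared by all three modules)."""
    return f + a * f


class MasgBlock(Module):
    """Bottleneck block: contrastive attention + dilated context + aux head."""

    def __init__(self, c_in: int, c_fg: int, c_bg: int, out_channels: int,
                 reduction: int, dilation_rates, num_classes: int,
                 rng: np.random.Generator):
        super().__init__()
        cp = out_channels
        if cp % 4:
            raise ValueError("embedding width must be divisible by 4")
        self.out_channels = cp
        self.embed_in = ConvBNReLU(c_in, cp, 1, rng)
        self.embed_fg = ConvBNReLU(c_fg, cp, 1, rng)
        self.embed_bg = ConvBNReLU(c_bg, cp, 1, rng)
        hidden = max(1, cp // reduction)
        self.att1 = Conv2d(2 * cp, hidden, 1, rng)
        self.att2 = Conv2d(hidden, cp, 1, rng)
        self.branches = [ConvBNReLU(cp, cp // 4, 3, rng, dilation=d)
                         for d in dilation_rates]
        self.reduce = ConvBNReLU(2 * cp, cp, 1, rng)
        self.aux1 = ConvBNReLU(cp, cp // 2, 3, rng)
        self.aux2 = Conv2d(cp // 2, num_classes, 3, rng, padding=1)

    # -- the stages of the construction, exposed for testing ----------------
    def contrastive_attention(self, f_in: Tensor, f_fg: Tensor, f_bg: Tensor):
        """Difference construction, attention map, residual fusion.

        Returns ``(F_diff, A, F_att)``.
        """
        if not (f_in.shape == f_fg.shape == f_bg.shape):
            raise ValueError("embedded references must share the input's shape")
        f_diff = nn.concat([f_in - f_fg, f_in - f_bg], axis=1)
        a = nn.sigmoid(self.att2(nn.relu(self.att1(f_diff))))
        return f_diff, a, residual_gate(f_in, a)

    def dilated_context(self, f_att: Tensor) -> Tensor:
        """Four parallel dilated 3x3 branches, concatenated with the input
        and reduced back to C' channels."""
        outs = [br(f_att) for br in self.branches]
        return self.reduce(nn.concat([f_att] + outs, axis=1))

    def aux_head(self, f_dec0: Tensor, out_hw: tuple[int, int]) -> Tensor:
        """Two convolutions then bilinear upsampling to the image grid."""
        return nn.bilinear_resize(self.aux2(self.aux1(f_dec0)), out_hw)

    def forward(self, f_enc4: Tensor, f_enc3: Tensor, f_stem: Tensor,
                out_hw: tuple[int, int]):
        """Return ``(F_dec0, F_aux)``."""
        hw = f_enc4.shape[2:]
        f_in = self.embed_in(f_enc4)
        f_fg = embed_reference(self.embed_fg, f_enc3, hw)
        f_bg = embed_reference(self.embed_bg, f_stem, hw)
        _, _, f_att = self.contrastive_attention(f_in, f_fg, f_bg)
        f_dec0 = self.dilated_context(f_att)
        return f_dec0, self.aux_head(f_dec0, out_hw)

    def complexity(self, h, w):
        m = (self.embed_in.complexity(h, w) + self.embed_fg.complexity(h, w)
             + self.embed_bg.complexity(h, w))
        m += self.att1.macs(h, w) + self.att2.macs(h, w)
        m += sum(br.complexity(h, w) for br in self.branches)
        m += self.reduce.complexity(h, w)
        m += self.aux1.complexity(h, w) + self.aux2.macs(h, w)
        return m
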