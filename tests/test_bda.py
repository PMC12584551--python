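"""Difference-aware skip fusion: SAVA gating, the embedding block, and the
full module, against brute-force oracles of the published construction."""

import numpy as np
import pytest

from dcceunet import nn
from dcceunet.bda import BdaBlock, Sava
from conftest import cast64


@pytest.fixture
def sava(rng):
    return cast64(Sava(4, reduction=2, rng=rng).eval())


@pytest.fixture
def block(rng):
    return cast64(BdaBlock(4, sava_reduction=2, rng=rng).eval())


def _sava_oracle(m: Sava, f: np.ndarray) -> np.ndarray:
    """Independent recomputation of the SAVA gating."""
    var = f.var(axis=(2, 3), keepdims=True)  # population variance
    w1, b1 = m.fc1.weight.data[:, :, 0, 0], m.fc1.bias.data
    w2, b2 = m.fc2.weight.data[:, :, 0, 0], m.fc2.bias.data
    h = np.maximum(np.einsum("oi,bixy->boxy", w1, var) + b1[None, :, None, None], 0)
    wgate = 1 / (1 + np.exp(-(np.einsum("oi,bixy->boxy", w2, h)
                              + b2[None, :, None, None])))
    smap = np.stack([f.mean(axis=1), f.max(axis=1)], axis=1)
    sp = np.pad(smap, ((0, 0), (0, 0), (3, 3), (3, 3)))
    k = m.spatial.weight.data
    b, _, hh, ww = f.shape
    conv = np.zeros((b, 1, hh, ww))
    for i in range(7):
        for j in range(7):
            conv[:, 0] += (k[0, 0, i, j] * sp[:, 0, i:i + hh, j:j + ww]
                           + k[0, 1, i, j] * sp[:, 1, i:i + hh, j:j + ww])
    sgate = 1 / (1 + np.exp(-(conv + m.spatial.bias.data[0])))
    return f * wgate * sgate


def test_sava_variance_of_toy_patch(sava):
    """The 2x2 patch [[1,3],[5,7]] has population variance 5, matching a
    mean-of-squares oracle."""
    f = np.array([[1.0, 3.0], [5.0, 7.0]])
    v_ref = (f ** 2).mean() - f.mean() ** 2
    assert v_ref == 5.0
    x = np.zeros((1, 4, 2, 2))
    x[0, 0] = f
    out = sava(nn.Tensor(x))
    assert np.allclose(out.data, _sava_oracle(sava, x), atol=1e-10)


def test_sava_constant_input_channel_gate_is_bias_path(sava):
    """Spatially constant maps have zero variance in every channel, so the
    channel gate collapses to the sigmoid of the bottleneck's bias path,
    identical for any constant level."""
    b1 = sava.fc1.bias.data
    w2, b2 = sava.fc2.weight.data[:, :, 0, 0], sava.fc2.bias.data
    expected = 1 / (1 + np.exp(-(w2 @ np.maximum(b1, 0) + b2)))
    for level in (2.0, -7.0):
        f = np.full((1, 4, 3, 3), level)
        out = sava(nn.Tensor(f)).data
        # out = f * wgate * sgate with sgate shared across channels; the
        # per-channel profile out_c / f must be proportional to `expected`
        profile = (out / f)[0, :, 1, 1]          # interior pixel, all channels
        ratio = profile / expected
        assert np.allclose(ratio, ratio[0], atol=1e-9)
        assert np.allclose(out, _sava_oracle(sava, f), atol=1e-10)


def test_sava_shapes_and_degenerate_input(sava, rng):
    x = rng.normal(size=(2, 4, 5, 3))
    assert sava(nn.Tensor(x)).shape == x.shape
    with pytest.raises(ValueError):
        sava(nn.Tensor(rng.normal(size=(1, 4, 1, 1))))


def test_sava_matches_oracle_on_random_input(sava, rng):
    x = rng.normal(size=(2, 4, 5, 5))
    assert np.allclose(sava(nn.Tensor(x)).data, _sava_oracle(sava, x), atol=1e-9)


def test_emb_zero_difference_gives_constant_gate(block, rng):
    """If the subtrahend equals the encoder feature, F_sub = 0 and the gate
    is the sigmoid of the BN bias: spatially constant."""
    f_sub = nn.Tensor(np.zeros((1, 4, 5, 5)))
    gate = block._gate(f_sub)
    assert np.allclose(gate.data, gate.data[..., :1, :1], atol=1e-12)
    assert (gate.data > 0).all() and (gate.data < 1).all()


def test_emb_matches_elementwise_oracle(block, rng):
    f_enc = rng.normal(size=(1, 4, 5, 5))
    f_dec = rng.normal(size=(1, 4, 5, 5))
    f_mod_enc, f_mod_dec = block.emb_block(nn.Tensor(f_enc), nn.Tensor(f_dec))

    def gate_oracle(f_sub):
        w = block.gate_conv.weight.data[:, :, 0, 0]
        z = np.einsum("oi,bixy->boxy", w, f_sub)
        gamma = block.gate_bn.weight.data[None, :, None, None]
        beta = block.gate_bn.bias.data[None, :, None, None]
        inv = 1 / np.sqrt(block.gate_bn.running_var + block.gate_bn.eps)
        zn = (z - block.gate_bn.running_mean[None, :, None, None]) \
            * inv[None, :, None, None] * gamma + beta
        return 1 / (1 + np.exp(-zn))

    ref_enc = f_enc * (1 + gate_oracle(f_enc - _sava_oracle(block.emb_sava, f_dec)))
    ref_dec = f_dec * (1 + gate_oracle(f_dec - _sava_oracle(block.emb_sava, f_enc)))
    assert np.allclose(f_mod_enc.data, ref_enc, atol=1e-9)
    assert np.allclose(f_mod_dec.data, ref_dec, atol=1e-9)
    with pytest.raises(ValueError):
        block.emb_block(nn.Tensor(f_enc), nn.Tensor(f_dec[:, :, :4]))


def test_gate_zero_recovers_residual_identity(block, rng):
    f = nn.Tensor(rng.normal(size=(1, 4, 5, 5)))
    from dcceunet.masg import residual_gate
    out = residual_gate(f, nn.Tensor(np.zeros_like(f.data)))
    assert np.array_equal(out.data, f.data)


def test_modulation_bound(block, rng):
    """|F_mod| <= 2 |F_enc| elementwise since the gate is bounded by 1."""
    f_enc = nn.Tensor(rng.normal(size=(2, 4, 6, 6)))
    f_dec = nn.Tensor(rng.normal(size=(2, 4, 6, 6)))
    f_mod_enc, f_mod_dec = block.emb_block(f_enc, f_dec)
    assert (np.abs(f_mod_enc.data) <= 2 * np.abs(f_enc.data) + 1e-12).all()
    assert (np.abs(f_mod_dec.data) <= 2 * np.abs(f_dec.data) + 1e-12).all()


def test_exact_null_for_identical_aligned_inputs(block, rng):
    """Identical encoder and aligned decoder features give F_bda == 0: the
    shared-weight pathways are symmetric and the final gating maps zero to
    zero."""
    f = nn.Tensor(rng.normal(size=(1, 4, 6, 6)))
    out = block(f, f)
    assert np.all(out.data == 0)


def test_bda_forward_matches_compositional_oracle(block, rng):
    """The full module agrees with a step-by-step scripted composition of
    the published equations."""
    f_enc = rng.normal(size=(1, 4, 5, 5))
    f_dec = rng.normal(size=(1, 4, 5, 5))
    out = block(nn.Tensor(f_enc), nn.Tensor(f_dec))
    f_mod_enc, f_mod_dec = block.emb_block(nn.Tensor(f_enc), nn.Tensor(f_dec))
    ref = _sava_oracle(block.final_sava, f_mod_enc.data - f_mod_dec.data)
    assert out.shape == (1, 4, 5, 5)
    assert np.allclose(out.data, ref, atol=1e-9)
    with pytest.raises(ValueError):
        block(nn.Tensor(rng.normal(size=(1, 3, 5, 5))), nn.Tensor(f_dec))
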