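"""Network assembly: shape contracts, determinism, complexity properties,
gradient flow, and forward equivalence with an independently coded U-Net."""

import numpy as np
import pytest
import scipy.signal

from dcceunet import (ModelConfig, build_model, count_complexity, nn,
                      total_loss)
from conftest import cast64


def test_forward_shapes_and_finiteness(tiny_cfg):
    model = build_model(tiny_cfg).eval()
    x = np.zeros((1, 1, 64, 64), dtype=np.float32)
    with nn.no_grad():
        seg, aux = model(x)
    assert seg.shape == (1, 2, 64, 64)
    assert aux.shape == (1, 2, 64, 64)
    assert np.isfinite(seg.data).all() and np.isfinite(aux.data).all()


def test_baseline_has_no_aux_output(tiny_cfg):
    model = build_model(tiny_cfg.with_variant("unet")).eval()
    with nn.no_grad():
        seg, aux = model(np.zeros((1, 1, 32, 32), dtype=np.float32))
    assert seg.shape == (1, 2, 32, 32)
    assert aux is None


def test_forward_is_deterministic_in_eval_mode(tiny_cfg, rng):
    model = build_model(tiny_cfg).eval()
    x = rng.random((1, 1, 32, 32)).astype(np.float32)
    with nn.no_grad():
        a, _ = model(x)
        b, _ = model(x)
    assert np.array_equal(a.data, b.data)


def test_invalid_inputs_rejected(tiny_cfg):
    model = build_model(tiny_cfg)
    with pytest.raises(ValueError):
        model(np.zeros((1, 1, 40, 40), dtype=np.float32))  # not /16
    with pytest.raises(ValueError):
        model(np.zeros((1, 3, 32, 32), dtype=np.float32))  # wrong channels
    with pytest.raises(ValueError):
        ModelConfig.tiny(input_size=(50, 50))
    with pytest.raises(ValueError):
        ModelConfig.tiny(cag_kernel=4)
    with pytest.raises(ValueError):
        ModelConfig.tiny(base_channels=(16, 16, 32, 64, 128))


def test_aux_logits_track_input_resolution(tiny_cfg, rng):
    """The auxiliary head upsamples the bottleneck by 16x back to the image
    grid, whatever the input size."""
    model = build_model(tiny_cfg).eval()
    for size in (32, 48):
        with nn.no_grad():
            _, aux = model(rng.random((1, 1, size, size)).astype(np.float32))
        assert aux.shape == (1, 2, size, size)


def test_ablation_parameter_monotonicity(tiny_cfg):
    counts = [build_model(tiny_cfg.with_variant(v)).num_parameters()
              for v in ("unet", "bda", "bda_cag", "full")]
    assert counts == sorted(counts) and len(set(counts)) == 4


def test_gmacs_scale_quadratically_for_fully_convolutional_variants(tiny_cfg):
    for v in ("unet", "full"):
        model = build_model(tiny_cfg.with_variant(v))
        small = count_complexity(model, (64, 64)).gmacs
        large = count_complexity(model, (128, 128)).gmacs
        # CAG's pooled context grid is resolution-capped, so allow its
        # constant-cost share; the backbone scales exactly 4x
        assert large / small == pytest.approx(4.0, rel=0.02)
        assert count_complexity(model, (64, 64)).params_millions == \
            count_complexity(model, (128, 128)).params_millions


def test_gradient_reaches_every_parameter(tiny_cfg, rng):
    """One backward pass of the full objective leaves no parameter without
    gradient signal."""
    model = build_model(tiny_cfg)
    x = rng.random((2, 1, 32, 32)).astype(np.float32)
    gt = (rng.random((2, 32, 32)) > 0.5).astype(np.int64)
    seg, aux = model(x)
    bundle = total_loss(seg, aux, gt, lambda_aux=0.4)
    bundle.tensor.backward()
    for name, p in model.named_parameters():
        assert p.grad is not None, f"no gradient for {name}"
        assert np.any(p.grad != 0), f"all-zero gradient for {name}"


# ---------------------------------------------------------------------------
# independent plain U-Net oracle
# ---------------------------------------------------------------------------

def _conv_np(x, w, b=None, pad=0):
    bs, ci, _, _ = x.shape
    co = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.stack([
        np.stack([
            sum(scipy.signal.correlate(xp[n, c], w[o, c], mode="valid")
                for c in range(ci)) + (b[o] if b is not None else 0.0)
            for o in range(co)])
        for n in range(bs)])
    return out


def _bn_eval_np(x, bn):
    inv = 1.0 / np.sqrt(bn.running_var + bn.eps)
    return ((x - bn.running_mean[None, :, None, None])
            * inv[None, :, None, None]
            * bn.weight.data[None, :, None, None]
            + bn.bias.data[None, :, None, None])


def _cbr_np(x, block, pad):
    return np.maximum(_bn_eval_np(_conv_np(x, block.conv.weight.data, pad=pad),
                                  block.bn), 0)


def _dconv_np(x, dc):
    return _cbr_np(_cbr_np(x, dc.c1, 1), dc.c2, 1)


def _maxpool_np(x):
    b, c, h, w = x.shape
    return x.reshape(b, c, h // 2, 2, w // 2, 2).max(axis=(3, 5))


def _bilinear_np(x, out_hw):
    """Direct per-pixel bilinear interpolation (half-pixel centres)."""
    b, c, h, w = x.shape
    ho, wo = out_hw
    out = np.zeros((b, c, ho, wo))
    for i in range(ho):
        sy = min(max((i + 0.5) * h / ho - 0.5, 0), h - 1)
        y0, fy = int(np.floor(sy)), sy - int(np.floor(sy))
        y1 = min(y0 + 1, h - 1)
        for j in range(wo):
            sx = min(max((j + 0.5) * w / wo - 0.5, 0), w - 1)
            x0, fx = int(np.floor(sx)), sx - int(np.floor(sx))
            x1 = min(x0 + 1, w - 1)
            out[:, :, i, j] = ((1 - fy) * (1 - fx) * x[:, :, y0, x0]
                               + (1 - fy) * fx * x[:, :, y0, x1]
                               + fy * (1 - fx) * x[:, :, y1, x0]
                               + fy * fx * x[:, :, y1, x1])
    return out


def test_baseline_forward_matches_independent_unet(rng):
    """With all module flags off, the network is a plain U-Net: an
    independently coded NumPy forward pass with the same weights agrees to
    machine tolerance on a 32x32 input."""
    cfg = ModelConfig.tiny(base_channels=(3, 5, 7, 9, 11), input_size=(32, 32),
                           masg_channels=8).with_variant("unet")
    model = cast64(build_model(cfg).eval())
    x = rng.normal(size=(1, 1, 32, 32))

    with nn.no_grad():
        seg, aux = model(nn.Tensor(x))
    assert aux is None

    f = _dconv_np(x, model.stem)
    feats = [f]
    for enc in model.encoders:
        f = _dconv_np(_maxpool_np(f), enc)
        feats.append(f)
    for lvl, dec in zip((3, 2, 1, 0), model.decoders):
        skip = feats[lvl]
        up = _bilinear_np(f, skip.shape[2:])
        aligned = _cbr_np(up, dec.proj, 0)
        f = _dconv_np(np.concatenate([aligned, skip], axis=1), dec.dconv)
    head = model.head
    ref = _conv_np(np.maximum(_conv_np(f, head.conv1.weight.data,
                                       head.conv1.bias.data, pad=1), 0),
                   head.conv2.weight.data, head.conv2.bias.data)
    assert np.allclose(seg.data, ref, atol=1e-9)
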