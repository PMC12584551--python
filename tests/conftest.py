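import numpy as np
import pytest

from dcceunet import ModelConfig, TrainConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_cfg():
    """Small full-model config for fast structural tests."""
    return ModelConfig.tiny(
        base_channels=(4, 8, 12, 16, 20), masg_channels=16,
        attention_reduction=2, sava_reduction=2,
        cag_expansion=2, cag_grid=8, cag_kernel=5,
        input_size=(32, 32),
    )


@pytest.fixture(scope="session")
def phantom_dir(tmp_path_factory):
    """A small phantom dataset shared across tests (30 pairs at 48x48)."""
    d = tmp_path_factory.mktemp("phantoms")
    generate_dataset(30, d, seed=7, image_size=(48, 48))
    return d


def cast64(module):
    """Promote a module's parameters and buffers to float64 (for oracle
    comparisons at tight tolerance)."""
    for p in module.parameters():
        p.data = p.data.astype(np.float64)
    for m in module.modules():
        for name, buf in list(m._buffers().items()):
            setattr(m, name, np.asarray(getattr(m, name), dtype=np.float64))
    return module


def numgrad(f, x, eps=1e-6):
    """Central finite-difference gradient of scalar-valued ``f`` w.r.t. the
    array ``x`` (mutated in place)."""
    g = np.zeros_like(x)
    flat, gf = x.reshape(-1), g.reshape(-1)
    for i in range(flat.size):
        old = flat[i]
        flat[i] = old + eps
        fp = f()
        flat[i] = old - eps
        fm = f()
        flat[i] = old
        gf[i] = (fp - fm) / (2 * eps)
    return g
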