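import numpy as np
import pytest

from freqvit.config import SynthSpec
from freqvit.synth import generate_dataset

TINY = dict(
    image_size=16,
    patch_size=4,
    embed_dim=16,
    depth=2,
    num_heads=2,
    se_reduction=4,
    num_classes=2,
)


@pytest.fixture
def tiny_kwargs():
    return dict(TINY)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_dataset():
    """40 synthetic 32x32 tiles, balanced, deterministic."""
    spec = SynthSpec(image_size=32, n_per_class=20, seed=11)
    return generate_dataset(spec)


def random_tokens(rng, n_tokens, dim, scale=1.0):
    return scale * rng.normal(size=(1, n_tokens, dim))


# ---- independent numpy references used as oracles in several test modules ----

def layernorm_ref(x, gamma, beta, eps=1e-6):
    mu = x.mean(axis=-1, keepdims=True)
    sd = np.sqrt(x.var(axis=-1, keepdims=True) + eps)
    return (x - mu) / sd * gamma + beta


def msa_ref(x, qkv_w, qkv_b, proj_w, proj_b, num_heads):
    """Direct loop-over-heads self-attention, independent of freqvit.nn."""
    b, t, d = x.shape
    hd = d // num_heads
    qkv = x @ qkv_w + qkv_b
    out = np.zeros((b, t, d))
    for h in range(num_heads):
        q = qkv[..., h * hd : (h + 1) * hd]
        k = qkv[..., d + h * hd : d + (h + 1) * hd]
        v = qkv[..., 2 * d + h * hd : 2 * d + (h + 1) * hd]
        scores = q @ k.transpose(0, 2, 1) / np.sqrt(hd)
        e = np.exp(scores - scores.max(axis=-1, keepdims=True))
        attn = e / e.sum(axis=-1, keepdims=True)
        out[..., h * hd : (h + 1) * hd] = attn @ v
    return out @ proj_w + proj_b
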