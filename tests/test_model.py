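import numpy as np
import pytest

from conftest import layernorm_ref, msa_ref

from freqvit.config import ModelConfig
from freqvit.model import EncoderBlock, FreqViT, PatchEmbed
from freqvit.training import loss_and_grad


def make_block(variant, rng_seed=0, **kwargs):
    cfg = ModelConfig.for_variant(variant, **kwargs)
    return cfg, EncoderBlock(cfg, np.random.default_rng(rng_seed), index=0)


def oracle_far(block, tokens, cfg, gate_fn=None):
    """Independent route: spatial-domain spectral residual + reference MSA."""
    t0, t = tokens[:, :1], tokens[:, 1:]
    if cfg.use_fft or cfg.use_se:
        y = layernorm_ref(t, block.ln_spec.gamma.value, block.ln_spec.beta.value)
        branch = y if gate_fn is None else gate_fn(y)
        x = np.concatenate([t0, t + branch], axis=1)
    else:
        x = tokens
    ln = layernorm_ref(x, block.ln_attn.gamma.value, block.ln_attn.beta.value)
    attn = msa_ref(
        ln,
        block.attn.qkv.w.value, block.attn.qkv.b.value,
        block.attn.proj.w.value, block.attn.proj.b.value,
        cfg.num_heads,
    )
    return x + attn


class TestPatchEmbed:
    @pytest.mark.parametrize(
        "size,patch,n_expected",
        [(224, 16, 196), (16, 16, 1), (64, 8, 64)],
    )
    def test_token_counts(self, size, patch, n_expected):
        cfg = ModelConfig(image_size=size, patch_size=patch, embed_dim=32, num_heads=4)
        pe = PatchEmbed(cfg, np.random.default_rng(0))
        img = np.random.default_rng(1).random((1, 3, size, size))
        tokens = pe.forward(img)
        assert tokens.shape == (1, n_expected + 1, 32)
        assert cfg.num_patches == n_expected

    def test_grid_shape(self):
        cfg = ModelConfig(image_size=64, patch_size=8, embed_dim=16, num_heads=2)
        assert cfg.grid_shape == (8, 8)

    def test_wrong_size_error_names_expectation(self, tiny_kwargs):
        cfg = ModelConfig(**tiny_kwargs)
        pe = PatchEmbed(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="16"):
            pe.forward(np.zeros((1, 3, 20, 20)))

    def test_positional_embedding_added(self, tiny_kwargs):
        cfg = ModelConfig(**tiny_kwargs)
        pe = PatchEmbed(cfg, np.random.default_rng(0))
        zero_img = np.zeros((1, 3, 16, 16))
        tokens = pe.forward(zero_img)
        expected = np.concatenate(
            [pe.cls_token.value[None], np.tile(pe.proj.b.value, (16, 1))]
        ) + pe.pos_embed.value
        assert np.allclose(tokens[0], expected)


class TestFarRefine:
    def test_b0_equals_plain_attention_block(self, tiny_kwargs, rng):
        cfg, block = make_block("B0", **tiny_kwargs)
        tokens = rng.normal(size=(2, 17, 16))
        out = block.far_refine(tokens)
        expected = oracle_far(block, tokens, cfg)
        assert np.allclose(out, expected, rtol=1e-6, atol=1e-8)

    def test_b1_reduces_to_t_plus_ln(self, tiny_kwargs, rng):
        # FFT round-trip with no gate: spectral branch output == LN(T)
        cfg, block = make_block("B1", **tiny_kwargs)
        tokens = rng.normal(size=(2, 17, 16))
        out = block.far_refine(tokens)
        expected = oracle_far(block, tokens, cfg, gate_fn=None)
        denom = np.abs(expected).max()
        assert np.abs(out - expected).max() / denom < 1e-4

    def test_full_reduces_to_gated_ln(self, tiny_kwargs, rng):
        cfg, block = make_block("full", rng_seed=5, **tiny_kwargs)
        # give the SE branch non-trivial weights
        r2 = np.random.default_rng(9)
        block.se_w1.value[...] = r2.normal(size=block.se_w1.value.shape)
        block.se_w2.value[...] = r2.normal(size=block.se_w2.value.shape)
        tokens = rng.normal(size=(2, 17, 16))

        def gate_fn(y):
            b, n, d = y.shape
            yg = y.transpose(0, 2, 1).reshape(b, d, 4, 4)
            desc = np.abs(np.fft.fft2(yg, axes=(-2, -1))).mean(axis=(2, 3))
            hid = np.maximum(desc @ block.se_w1.value + block.se_b1.value, 0)
            gate = 1 / (1 + np.exp(-(hid @ block.se_w2.value + block.se_b2.value)))
            return y * gate[:, None, :]

        out = block.far_refine(tokens)
        expected = oracle_far(block, tokens, cfg, gate_fn=gate_fn)
        assert np.abs(out - expected).max() / np.abs(expected).max() < 1e-4

    def test_class_token_skips_spectral_branch(self, tiny_kwargs, rng):
        # identical patch tokens, different class tokens: the spectral residual
        # on the patches must be unaffected by the class token content
        cfg, block = make_block("full", **tiny_kwargs)
        tokens_a = rng.normal(size=(1, 17, 16))
        tokens_b = tokens_a.copy()
        tokens_b[:, 0] += 10.0
        t = tokens_a[:, 1:]
        y = block.ln_spec.forward(t)
        u_a = t + block._spectral_branch(y)
        y2 = block.ln_spec.forward(tokens_b[:, 1:])
        u_b = tokens_b[:, 1:] + block._spectral_branch(y2)
        assert np.array_equal(u_a, u_b)

    def test_permutation_sensitivity(self, tiny_kwargs, rng):
        # shuffling patch tokens changes the gated spectral branch output
        cfg, block = make_block("full", rng_seed=3, **tiny_kwargs)
        r2 = np.random.default_rng(1)
        block.se_w1.value[...] = r2.normal(size=block.se_w1.value.shape)
        block.se_w2.value[...] = r2.normal(size=block.se_w2.value.shape)
        y = rng.normal(size=(1, 16, 16))
        out = block._spectral_branch(y)
        perm = np.random.default_rng(2).permutation(16)
        out_perm = block._spectral_branch(y[:, perm])
        assert not np.allclose(out[:, perm], out_perm, atol=1e-8)

    def test_nonfinite_raises_with_block_index(self, tiny_kwargs, rng):
        cfg, block = make_block("B1", **tiny_kwargs)
        block.index = 7
        tokens = rng.normal(size=(1, 17, 16))
        tokens[0, 3, 2] = np.nan
        with pytest.raises((FloatingPointError, ValueError), match="(block 7|non-finite)"):
            block.far_refine(tokens)


class TestEncoderBlock:
    def test_shape_preserved(self, tiny_kwargs, rng):
        _, block = make_block("full", **tiny_kwargs)
        tokens = rng.normal(size=(3, 17, 16))
        assert block.forward(tokens).shape == (3, 17, 16)

    def test_zero_mlp_is_pure_residual(self, tiny_kwargs, rng):
        _, block = make_block("B0", **tiny_kwargs)
        block.fc2.w.value[...] = 0.0
        block.fc2.b.value[...] = 0.0
        tokens = rng.normal(size=(2, 17, 16))
        zbar = block.far_refine(tokens)
        assert np.array_equal(block.forward(tokens), zbar)

    def test_mlp_hidden_width_is_four_times_dim(self):
        cfg = ModelConfig()  # defaults: D=768, mlp_ratio=4
        block = EncoderBlock(cfg, np.random.default_rng(0))
        assert block.fc1.w.value.shape == (768, 3072)


class TestForward:
    def test_probs_sum_to_one(self, tiny_kwargs, rng):
        model = FreqViT(ModelConfig(**tiny_kwargs), seed=0)
        probs = model.predict_proba(rng.random((4, 3, 16, 16)))
        assert probs.shape == (4, 2)
        assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-6

    def test_zero_head_uniform(self, tiny_kwargs, rng):
        model = FreqViT(ModelConfig(**tiny_kwargs), seed=0)
        model.head.w.value[...] = 0.0
        model.head.b.value[...] = 0.0
        probs = model.predict_proba(rng.random((2, 3, 16, 16)))
        assert np.allclose(probs, 0.5)

    def test_deterministic_in_eval_mode(self, tiny_kwargs, rng):
        model = FreqViT(ModelConfig(**tiny_kwargs), seed=0)
        img = rng.random((1, 3, 16, 16))
        batch = np.concatenate([img, img])
        probs = model.predict_proba(batch)
        assert np.array_equal(probs[0], probs[1])
        assert np.array_equal(model.predict_proba(img), model.predict_proba(img))


class TestExtractFeature:
    def test_length_is_embed_dim(self, tiny_kwargs, rng):
        model = FreqViT(ModelConfig(**tiny_kwargs), seed=0)
        feat = model.extract_feature(rng.random((2, 3, 16, 16)))
        assert feat.shape == (2, 16)
        assert np.isfinite(feat).all()

    def test_bitwise_repeatable(self, tiny_kwargs, rng):
        model = FreqViT(ModelConfig(**tiny_kwargs), seed=0)
        img = rng.random((1, 3, 16, 16))
        assert np.array_equal(model.extract_feature(img), model.extract_feature(img))

    def test_logits_affine_in_feature(self, tiny_kwargs, rng):
        model = FreqViT(ModelConfig(**tiny_kwargs), seed=0)
        img = rng.random((2, 3, 16, 16))
        feat = model.extract_feature(img)
        logits = model.forward(img)
        assert np.allclose(logits, feat @ model.head.w.value + model.head.b.value)


class TestGradients:
    @pytest.mark.parametrize("variant", ["B0", "B1", "B2", "full"])
    def test_finite_difference_agreement(self, variant, tiny_kwargs):
        cfg = ModelConfig.for_variant(variant, **tiny_kwargs)
        model = FreqViT(cfg, seed=3)
        rng = np.random.default_rng(5)
        x = rng.random((2, 3, 16, 16))
        y = np.array([0, 1])
        logits = model.forward(x)
        _, g = loss_and_grad(logits, y)
        model.zero_grad()
        model.backward(g)
        eps = 1e-6
        picker = np.random.default_rng(7)
        checked = 0
        for p in model.params():
            flat, gflat = p.value.reshape(-1), p.grad.reshape(-1)
            i = int(picker.integers(flat.size))
            orig = flat[i]
            flat[i] = orig + eps
            lp, _ = loss_and_grad(model.forward(x), y)
            flat[i] = orig - eps
            lm, _ = loss_and_grad(model.forward(x), y)
            flat[i] = orig
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - gflat[i]) <= 1e-4 * max(1.0, abs(fd)), (
                f"{variant}: fd {fd} vs analytic {gflat[i]}"
            )
            checked += 1
        assert checked > 10

    def test_single_step_decreases_loss(self, tiny_kwargs):
        # smoke property at lr 1e-5 with all flags on
        cfg = ModelConfig.for_variant("full", **tiny_kwargs)
        model = FreqViT(cfg, seed=0)
        rng = np.random.default_rng(1)
        x = rng.random((8, 3, 16, 16))
        y = np.array([0, 1] * 4)
        loss0, g = loss_and_grad(model.forward(x), y)
        model.zero_grad()
        model.backward(g)
        for p in model.params():
            p.value -= 1e-5 * p.grad
        loss1, _ = loss_and_grad(model.forward(x), y)
        assert loss1 < loss0


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_kwargs, rng, tmp_path):
        model = FreqViT(ModelConfig(**tiny_kwargs), seed=0)
        path = str(tmp_path / "ckpt.fvz")
        model.save(path)
        loaded = FreqViT.load(path)
        img = rng.random((2, 3, 16, 16))
        assert np.array_equal(model.forward(img), loaded.forward(img))
        assert loaded.cfg == model.cfg

    def test_shape_validation(self, tiny_kwargs):
        model = FreqViT(ModelConfig(**tiny_kwargs), seed=0)
        arrays = model.copy_weights()
        arrays[0] = arrays[0][:, :-1]
        with pytest.raises(ValueError, match="shape mismatch"):
            model.load_state_arrays(arrays)


class TestConfigValidation:
    def test_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(image_size=50, patch_size=16)
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(embed_dim=100, num_heads=7)

    def test_variant_mapping(self):
        assert ModelConfig.for_variant("B0").variant == "B0"
        assert ModelConfig.for_variant("B1").variant == "B1"
        assert ModelConfig.for_variant("B2").variant == "B2"
        assert ModelConfig.for_variant("full").variant == "full"
        with pytest.raises(ValueError, match="unknown variant"):
            ModelConfig.for_variant("B3")
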