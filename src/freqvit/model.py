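"""Fourier-guided attention encoder.

The encoder is a pre-norm vision transformer whose blocks prepend a spectral
refinement stage to self-attention: patch tokens are layer-normalized,
re-laid-out on their 2-D patch grid, pushed through a per-channel gated
Fourier round-trip, and added back residually.  The class token bypasses the
spectral stage and is re-attached before attention.

Implemented in NumPy with explicit backward passes (see :mod:`freqvit.nn`);
the whole model is deterministic given its initialization seed.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict
from typing import Dict, List

import numpy as np

from .config import ModelConfig
from .nn import (
    AdamW,
    LayerNorm,
    Linear,
    Module,
    MultiHeadSelfAttention,
    Param,
    gelu,
    gelu_grad,
    softmax,
    trunc_normal,
)

_EPS_MAG = 1e-12


class PatchEmbed(Module):
    """Non-overlapping P x P patch flattening + linear projection + class/pos tokens.

    Flattening order inside a patch is row-major over pixels with the three
    colour channels interleaved last, i.e. ``(row, col, channel)``; this is a
    fixed convention so checkpoints are portable.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        p = cfg.patch_size
        self.proj = Linear(p * p * 3, cfg.embed_dim, rng)
        self.cls_token = Param(trunc_normal(rng, (cfg.embed_dim,)), decay=False)
        self.pos_embed = Param(
            trunc_normal(rng, (cfg.num_patches + 1, cfg.embed_dim)), decay=False
        )
        self._b = None

    def _patchify(self, images: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        b = images.shape[0]
        g, p = cfg.grid_size, cfg.patch_size
        x = images.reshape(b, 3, g, p, g, p)
        x = x.transpose(0, 2, 4, 3, 5, 1)  # (b, Hp, Wp, p, p, 3)
        return x.reshape(b, cfg.num_patches, p * p * 3)

    def forward(self, images: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[None]
        s = cfg.image_size
        if images.shape[1:] != (3, s, s):
            raise ValueError(
                f"expected input of shape (B, 3, {s}, {s}), got {images.shape}"
            )
        if not np.isfinite(images).all():
            raise ValueError("non-finite values in input image")
        self._b = images.shape[0]
        tokens = self.proj.forward(self._patchify(images))  # (b, N, D)
        cls = np.broadcast_to(
            self.cls_token.value, (self._b, 1, cfg.embed_dim)
        )
        return np.concatenate([cls, tokens], axis=1) + self.pos_embed.value

    def backward(self, g: np.ndarray) -> None:
        self.pos_embed.grad += g.sum(axis=0)
        self.cls_token.grad += g[:, 0].sum(axis=0)
        self.proj.backward(g[:, 1:])

    def params(self) -> List[Param]:
        return self.proj.params() + [self.cls_token, self.pos_embed]


class EncoderBlock(Module):
    """One encoder block: spectral refinement -> self-attention -> MLP (all residual)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, index: int = 0):
        d = cfg.embed_dim
        self.cfg = cfg
        self.index = index
        self.spectral_active = cfg.use_fft or cfg.use_se
        if self.spectral_active:
            self.ln_spec = LayerNorm(d)
        if cfg.use_se:
            hidden = cfg.se_hidden
            self.se_w1 = Param(trunc_normal(rng, (d, hidden)))
            self.se_b1 = Param(np.zeros(hidden), decay=False)
            self.se_w2 = Param(trunc_normal(rng, (hidden, d)))
            self.se_b2 = Param(np.zeros(d), decay=False)
        if cfg.use_fft and cfg.use_spectral_filter:
            hp, wp = cfg.grid_shape
            self.filter_re = Param(np.ones((d, hp, wp)), decay=False)
            self.filter_im = Param(np.zeros((d, hp, wp)), decay=False)
        self.ln_attn = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, cfg.num_heads, rng)
        self.ln_mlp = LayerNorm(d)
        hidden = cfg.mlp_ratio * d
        self.fc1 = Linear(d, hidden, rng)
        self.fc2 = Linear(hidden, d, rng)
        self._cache: Dict = {}

    # ----- spectral residual: U = T + IFFT(G(FFT(LN(T)))) -----

    def _se_forward(self, desc: np.ndarray) -> np.ndarray:
        pre1 = desc @ self.se_w1.value + self.se_b1.value
        hid = np.maximum(pre1, 0.0)
        logits = hid @ self.se_w2.value + self.se_b2.value
        gate = 1.0 / (1.0 + np.exp(-logits))
        self._cache["se"] = (desc, pre1, hid, gate)
        return gate

    def _se_backward(self, d_gate: np.ndarray) -> np.ndarray:
        desc, pre1, hid, gate = self._cache["se"]
        d_logits = d_gate * gate * (1.0 - gate)
        self.se_w2.grad += hid.T @ d_logits
        self.se_b2.grad += d_logits.sum(axis=0)
        d_hid = d_logits @ self.se_w2.value.T
        d_pre1 = d_hid * (pre1 > 0.0)
        self.se_w1.grad += desc.T @ d_pre1
        self.se_b1.grad += d_pre1.sum(axis=0)
        return d_pre1 @ self.se_w1.value.T

    def _spectral_branch(self, patch_tokens: np.ndarray) -> np.ndarray:
        """Branch output for layer-normalized patch tokens ``Y`` of shape (b, N, D)."""
        cfg = self.cfg
        hp, wp = cfg.grid_shape
        b, n, d = patch_tokens.shape
        yg = patch_tokens.transpose(0, 2, 1).reshape(b, d, hp, wp)
        cache = self._cache
        cache["yg"] = yg
        if cfg.use_fft:
            z = np.fft.fft2(yg, axes=(-2, -1))
            if cfg.use_spectral_filter:
                filt = self.filter_re.value + 1j * self.filter_im.value
                z = z * filt
            cache["z"] = z
            if cfg.use_se:
                mag = np.abs(z)
                desc = mag.mean(axis=(2, 3))  # (b, d)
                cache["mag"] = mag
                gate = self._se_forward(desc)
                zg = z * gate[:, :, None, None]
                cache["gate"] = gate
            else:
                zg = z
            out = np.fft.ifft2(zg, axes=(-2, -1))
            resid = float(np.abs(out.imag).max())
            scale = max(float(np.abs(out.real).max()), 1.0)
            if not cfg.use_spectral_filter and resid > 1e-5 * scale:
                raise FloatingPointError(
                    f"block {self.index}: imaginary residue {resid:.3g} in spectral branch"
                )
            out = out.real
        else:  # SE only: gate from spatial magnitude summary
            desc = np.abs(yg).mean(axis=(2, 3))
            gate = self._se_forward(desc)
            out = yg * gate[:, :, None, None]
            cache["gate"] = gate
        return out.reshape(b, d, n).transpose(0, 2, 1)

    def _spectral_branch_backward(self, g_tokens: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        hp, wp = cfg.grid_shape
        nsp = hp * wp
        b, n, d = g_tokens.shape
        gu = g_tokens.transpose(0, 2, 1).reshape(b, d, hp, wp)
        cache = self._cache
        yg = cache["yg"]
        if cfg.use_fft:
            # adjoint of Re(ifft2(.)) is fft2(.)/nsp in the dL/dRe + i dL/dIm convention
            d_zg = np.fft.fft2(gu, axes=(-2, -1)) / nsp
            if cfg.use_se:
                z, gate = cache["z"], cache["gate"]
                d_gate = np.real(d_zg * np.conj(z)).sum(axis=(2, 3))
                d_z = d_zg * gate[:, :, None, None]
                d_desc = self._se_backward(d_gate)
                mag = cache["mag"]
                d_z += (d_desc[:, :, None, None] / nsp) * z / np.maximum(mag, _EPS_MAG)
            else:
                d_z = d_zg
            if cfg.use_spectral_filter:
                filt = self.filter_re.value + 1j * self.filter_im.value
                d_filt = (d_z * np.conj(np.fft.fft2(yg, axes=(-2, -1)))).sum(axis=0)
                self.filter_re.grad += d_filt.real
                self.filter_im.grad += d_filt.imag
                d_z = d_z * np.conj(filt)
            d_yg = nsp * np.real(np.fft.ifft2(d_z, axes=(-2, -1)))
        else:
            gate = cache["gate"]
            d_gate = (gu * yg).sum(axis=(2, 3))
            d_yg = gu * gate[:, :, None, None]
            d_desc = self._se_backward(d_gate)
            d_yg += (d_desc[:, :, None, None] / nsp) * np.sign(yg)
        return d_yg.reshape(b, d, n).transpose(0, 2, 1)

    # ----- public stages -----

    def far_refine(self, tokens: np.ndarray) -> np.ndarray:
        """Spectral residual on patch tokens, then pre-norm attention residual."""
        if self.spectral_active:
            t = tokens[:, 1:]
            y = self.ln_spec.forward(t)
            branch = self._spectral_branch(y)
            u = t + branch
            x = np.concatenate([tokens[:, :1], u], axis=1)
        else:
            x = tokens
        attn_out = self.attn.forward(self.ln_attn.forward(x))
        out = x + attn_out
        if not np.isfinite(out).all():
            raise FloatingPointError(f"block {self.index}: non-finite activations")
        return out

    def far_refine_backward(self, g: np.ndarray) -> np.ndarray:
        g_x = g + self.ln_attn.backward(self.attn.backward(g))
        if not self.spectral_active:
            return g_x
        g_cls = g_x[:, :1]
        g_u = g_x[:, 1:]
        g_y = self._spectral_branch_backward(g_u)
        g_t = g_u + self.ln_spec.backward(g_y)
        return np.concatenate([g_cls, g_t], axis=1)

    def forward(self, tokens: np.ndarray) -> np.ndarray:
        zbar = self.far_refine(tokens)
        h = self.fc1.forward(self.ln_mlp.forward(zbar))
        self._cache["mlp_pre"] = h
        out = zbar + self.fc2.forward(gelu(h))
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        g_h = self.fc2.backward(g) * gelu_grad(self._cache["mlp_pre"])
        g_zbar = g + self.ln_mlp.backward(self.fc1.backward(g_h))
        return self.far_refine_backward(g_zbar)

    def params(self) -> List[Param]:
        out: List[Param] = []
        if self.spectral_active:
            out += self.ln_spec.params()
        if self.cfg.use_se:
            out += [self.se_w1, self.se_b1, self.se_w2, self.se_b2]
        if self.cfg.use_fft and self.cfg.use_spectral_filter:
            out += [self.filter_re, self.filter_im]
        out += self.ln_attn.params() + self.attn.params()
        out += self.ln_mlp.params() + self.fc1.params() + self.fc2.params()
        return out


class FreqViT(Module):
    """The full encoder with classification head and feature-extraction mode."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.seed = seed
        self.patch_embed = PatchEmbed(cfg, rng)
        self.blocks = [EncoderBlock(cfg, rng, index=i) for i in range(cfg.depth)]
        self.final_ln = LayerNorm(cfg.embed_dim) if cfg.final_norm else None
        self.head = Linear(cfg.embed_dim, cfg.num_classes, rng)
        self._drop_rng = np.random.default_rng(seed + 1)
        self._cache: Dict = {}

    # ----- forward / backward -----

    def forward_tokens(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        tokens = self.patch_embed.forward(images)
        drop = self.cfg.drop_rate if train else 0.0
        masks = []
        for blk in self.blocks:
            tokens = blk.forward(tokens)
            if drop > 0.0:
                m = (self._drop_rng.random(tokens.shape) >= drop) / (1.0 - drop)
                tokens = tokens * m
                masks.append(m)
        self._cache["drop_masks"] = masks
        if self.final_ln is not None:
            tokens = np.concatenate(
                [self.final_ln.forward(tokens[:, :1]), tokens[:, 1:]], axis=1
            )
        return tokens

    def forward(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        """Class logits, shape (B, C)."""
        tokens = self.forward_tokens(images, train=train)
        feat = tokens[:, 0]
        self._cache["n_tokens"] = tokens.shape[1]
        return self.head.forward(feat)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return softmax(self.forward(images), axis=-1)

    def extract_feature(self, images: np.ndarray) -> np.ndarray:
        """Final class token after the (optional) final norm; shape (B, D)."""
        return self.forward_tokens(images, train=False)[:, 0]

    def backward(self, g_logits: np.ndarray) -> None:
        g_feat = self.head.backward(g_logits)
        b = g_feat.shape[0]
        g_tokens = np.zeros((b, self._cache["n_tokens"], self.cfg.embed_dim))
        g_tokens[:, 0] = g_feat
        if self.final_ln is not None:
            g_tokens = np.concatenate(
                [self.final_ln.backward(g_tokens[:, :1]), g_tokens[:, 1:]], axis=1
            )
        masks = self._cache.get("drop_masks") or []
        for i, blk in enumerate(reversed(self.blocks)):
            if masks:
                g_tokens = g_tokens * masks[len(self.blocks) - 1 - i]
            g_tokens = blk.backward(g_tokens)
        self.patch_embed.backward(g_tokens)

    def params(self) -> List[Param]:
        out = self.patch_embed.params()
        for blk in self.blocks:
            out += blk.params()
        if self.final_ln is not None:
            out += self.final_ln.params()
        out += self.head.params()
        return out

    # ----- checkpointing -----

    def state_arrays(self) -> List[np.ndarray]:
        return [p.value for p in self.params()]

    def load_state_arrays(self, arrays: List[np.ndarray]) -> None:
        ps = self.params()
        if len(arrays) != len(ps):
            raise ValueError(f"expected {len(ps)} arrays, got {len(arrays)}")
        for p, a in zip(ps, arrays):
            if p.value.shape != a.shape:
                raise ValueError(
                    f"shape mismatch: parameter {p.value.shape} vs checkpoint {a.shape}"
                )
            p.value[...] = a

    def save(self, path: str) -> None:
        cfg_json = json.dumps(asdict(self.cfg))
        arrays = {f"p{i:04d}": a for i, a in enumerate(self.state_arrays())}
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", cfg_json)
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str) -> "FreqViT":
        with zipfile.ZipFile(path) as zf:
            cfg = ModelConfig(**json.loads(zf.read("config.json")))
            with zf.open("weights.npz") as fh:
                npz = np.load(io.BytesIO(fh.read()))
                arrays = [npz[k] for k in sorted(npz.files)]
        model = cls(cfg)
        model.load_state_arrays(arrays)
        return model

    def copy_weights(self) -> List[np.ndarray]:
        return [p.value.copy() for p in self.params()]


def build_optimizer(model: FreqViT, lr: float, weight_decay: float) -> AdamW:
    return AdamW(model.params(), lr=lr, weight_decay=weight_decay)
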