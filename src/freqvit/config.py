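"""Configuration dataclasses shared across the encoder, trainer, and data generator."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Tuple

import yaml


@dataclass
class ModelConfig:
    """Hyperparameters of the spectral-refinement encoder.

    The ``use_fft`` / ``use_se`` flags select the ablation variant:

    ==========  ==========  =========
    use_fft     use_se      variant
    ==========  ==========  =========
    False       False       B0 (plain pre-norm ViT block)
    True        False       B1 (spectral round-trip only)
    False       True        B2 (channel gate in the spatial domain)
    True        True        full (spectral gate)
    ==========  ==========  =========
    """

    image_size: int = 224
    patch_size: int = 16
    embed_dim: int = 768
    depth: int = 4
    num_heads: int = 12
    mlp_ratio: int = 4
    se_reduction: int = 16
    num_classes: int = 2
    use_fft: bool = True
    use_se: bool = True
    use_spectral_filter: bool = False
    final_norm: bool = True
    drop_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.image_size % self.patch_size != 0:
            raise ValueError(
                f"image_size ({self.image_size}) must be divisible by "
                f"patch_size ({self.patch_size})"
            )
        if self.embed_dim % self.num_heads != 0:
            raise ValueError(
                f"embed_dim ({self.embed_dim}) must be divisible by "
                f"num_heads ({self.num_heads})"
            )
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be >= 1")
        if not (0.0 <= self.drop_rate < 1.0):
            raise ValueError("drop_rate must be in [0, 1)")

    @property
    def grid_size(self) -> int:
        return self.image_size // self.patch_size

    @property
    def num_patches(self) -> int:
        return self.grid_size ** 2

    @property
    def grid_shape(self) -> Tuple[int, int]:
        return (self.grid_size, self.grid_size)

    @property
    def se_hidden(self) -> int:
        # floor with a minimum of one unit so extreme reductions stay valid
        return max(1, self.embed_dim // self.se_reduction)

    @property
    def variant(self) -> str:
        return {
            (False, False): "B0",
            (True, False): "B1",
            (False, True): "B2",
            (True, True): "full",
        }[(self.use_fft, self.use_se)]

    @classmethod
    def for_variant(cls, variant: str, **kwargs) -> "ModelConfig":
        flags = {
            "B0": (False, False),
            "B1": (True, False),
            "B2": (False, True),
            "full": (True, True),
        }
        if variant not in flags:
            raise ValueError(f"unknown variant {variant!r}; expected one of {sorted(flags)}")
        use_fft, use_se = flags[variant]
        return cls(use_fft=use_fft, use_se=use_se, **kwargs)


@dataclass
class TrainConfig:
    """Optimization settings (AdamW with decoupled weight decay)."""

    epochs: int = 100
    lr: float = 1e-4
    weight_decay: float = 5e-2
    batch_size: int = 32
    seed: int = 0
    augment: bool = True
    val_fraction: float = 0.2
    cosine_schedule: bool = False

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# Optical-density vectors in Beer-Lambert space for the two emulated stains
# (nuclear / basophilic and cytoplasmic / eosinophilic absorption profiles).
DEFAULT_STAIN_MATRIX: Tuple[Tuple[float, float, float], Tuple[float, float, float]] = (
    (0.65, 0.70, 0.29),
    (0.07, 0.99, 0.11),
)


@dataclass
class SynthSpec:
    """Two-class texture generator settings.

    Class 0 emulates benign tissue (smoother field, rounder structures) and
    class 1 emulates malignant tissue (flatter power spectrum, added
    high-frequency speckle, rougher boundaries).  ``beta_*`` is the power-law
    slope of the random field's power spectrum; the benign slope must exceed
    the malignant one so the class signal lives in the upper frequencies.
    """

    image_size: int = 64
    n_per_class: int = 200
    beta_benign: float = 3.5
    beta_malignant: float = 1.6
    blob_count_benign: Tuple[int, int] = (3, 6)
    blob_count_malignant: Tuple[int, int] = (8, 14)
    blob_radius_benign: Tuple[float, float] = (0.08, 0.14)
    blob_radius_malignant: Tuple[float, float] = (0.05, 0.09)
    blob_eccentricity_benign: Tuple[float, float] = (1.0, 1.4)
    blob_eccentricity_malignant: Tuple[float, float] = (1.8, 3.2)
    speckle_benign: float = 0.05
    speckle_malignant: float = 0.11
    roughness_benign: float = 0.05
    roughness_malignant: float = 0.45
    gamma_range: Tuple[float, float] = (0.7, 1.4)
    stain_matrix: Tuple[Tuple[float, float, float], Tuple[float, float, float]] = (
        DEFAULT_STAIN_MATRIX
    )
    seed: int = 0
    allow_inverted_spectra: bool = False

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.beta_benign <= self.beta_malignant and not self.allow_inverted_spectra:
            raise ValueError(
                "beta_benign must exceed beta_malignant (benign = smoother field); "
                "set allow_inverted_spectra=True to override"
            )


def _coerce(cls, mapping: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise KeyError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


def load_run_config(path: str) -> dict:
    """Parse a YAML run file with optional ``model``/``train``/``synth`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    if "model" in raw:
        out["model"] = _coerce(ModelConfig, dict(raw["model"]))
    if "train" in raw:
        out["train"] = _coerce(TrainConfig, dict(raw["train"]))
    if "synth" in raw:
        s = dict(raw["synth"])
        for key, val in list(s.items()):
            if isinstance(val, list):
                s[key] = tuple(tuple(v) if isinstance(v, list) else v for v in val)
        out["synth"] = _coerce(SynthSpec, s)
    out["extra"] = {k: v for k, v in raw.items() if k not in ("model", "train", "synth")}
    return out


def dump_run_config(path: str, model=None, train=None, synth=None, extra=None) -> None:
    """Write the fully resolved configuration next to a run's outputs."""
    doc = {}
    if model is not None:
        doc["model"] = dataclasses.asdict(model)
    if train is not None:
        doc["train"] = dataclasses.asdict(train)
    if synth is not None:
        d = dataclasses.asdict(synth)
        d["stain_matrix"] = [list(row) for row in d["stain_matrix"]]
        for key in (
            "blob_count_benign",
            "blob_count_malignant",
            "blob_eccentricity_benign",
            "blob_eccentricity_malignant",
        ):
            d[key] = list(d[key])
        doc["synth"] = d
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
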