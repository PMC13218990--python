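"""Synthetic two-class H&E-like texture tiles.

Class 0 ("benign-like") tiles are built on a smooth power-law random field
with a few round gland-like depressions; class 1 ("malignant-like") tiles use
a flatter spectrum, more and more eccentric blobs with rough boundaries, and
added high-frequency speckle.  The class signal therefore lives partly in the
upper spatial frequencies, which is the property the spectral branch of the
encoder is meant to exploit.

Colours come from Beer-Lambert mixing of two optical-density stain vectors
(nuclear and cytoplasmic absorption), giving plausibly H&E-looking RGB tiles.
"""

from __future__ import annotations

import csv
import os
from typing import Sequence, Tuple

import numpy as np
from PIL import Image

from .config import SynthSpec

__all__ = [
    "spectral_field",
    "generate_dataset",
    "save_dataset",
    "load_image_dataset",
    "high_freq_fraction",
    "luma",
]


def spectral_field(size: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian random field with power spectrum ~ |f|^-beta, min-max scaled to [0,1].

    White noise is shaped in the frequency domain with amplitude |f|^(-beta/2);
    the DC component is zeroed so the field is centred before normalization.
    """
    if size < 16:
        raise ValueError("size must be >= 16")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    noise = rng.normal(size=(size, size))
    fx = np.fft.fftfreq(size)
    fy = np.fft.fftfreq(size)
    r = np.sqrt(fx[None, :] ** 2 + fy[:, None] ** 2)
    amp = np.zeros_like(r)
    nz = r > 0
    amp[nz] = r[nz] ** (-beta / 2.0)
    field = np.fft.ifft2(np.fft.fft2(noise) * amp).real
    lo, hi = field.min(), field.max()
    if hi - lo < 1e-12:
        return np.zeros_like(field)
    return (field - lo) / (hi - lo)


def _rank_normalize(field: np.ndarray) -> np.ndarray:
    """Monotone remap of field values to a uniform marginal on [0, 1].

    Preserves spatial arrangement (hence the spectral class signal) while
    removing the field's marginal distribution as a trivial histogram cue.
    """
    ranks = field.ravel().argsort().argsort().astype(np.float64)
    return (ranks / max(ranks.size - 1, 1)).reshape(field.shape)


def _blob_maps(
    size: int,
    count_range: Tuple[int, int],
    radius_range: Tuple[float, float],
    ecc_range: Tuple[float, float],
    roughness: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Soft interior mask and boundary-ring map for a set of elliptical blobs."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    interior = np.zeros((size, size))
    ring = np.zeros((size, size))
    n_blobs = int(rng.integers(count_range[0], count_range[1] + 1))
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, size, size=2)
        r_major = size * rng.uniform(*radius_range)
        ecc = rng.uniform(*ecc_range)
        r_minor = r_major / ecc
        phi = rng.uniform(0, 2 * np.pi)
        dy, dx = yy - cy, xx - cx
        xr = np.cos(phi) * dx + np.sin(phi) * dy
        yr = -np.sin(phi) * dx + np.cos(phi) * dy
        d = np.sqrt((xr / r_major) ** 2 + (yr / r_minor) ** 2)
        if roughness > 0:
            theta = np.arctan2(yr, xr)
            wobble = np.zeros_like(theta)
            for m in range(2, 6):
                wobble += rng.normal() / m * np.sin(m * theta + rng.uniform(0, 2 * np.pi))
            d = d * (1.0 + roughness * 0.5 * wobble)
        interior = np.maximum(
            interior, 1.0 / (1.0 + np.exp(np.clip((d - 1.0) / 0.08, -50.0, 50.0)))
        )
        ring = np.maximum(ring, np.exp(-(((d - 1.0) / 0.10) ** 2)))
    return interior, ring


def _render_tile(
    size: int,
    beta: float,
    count_range: Tuple[int, int],
    radius_range: Tuple[float, float],
    ecc_range: Tuple[float, float],
    speckle: float,
    roughness: float,
    gamma_range: Tuple[float, float],
    stain_matrix: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    base = _rank_normalize(spectral_field(size, beta, rng))
    interior, ring = _blob_maps(
        size, count_range, radius_range, ecc_range, roughness, rng
    )
    speckle_noise = rng.normal(size=(size, size))

    # stain concentration maps (Beer-Lambert optical densities); the speckle is
    # signed so it perturbs the spectrum without shifting the mean intensity
    cyto = (0.30 + 0.55 * base) * (1.0 - 0.65 * interior)
    nuc = np.clip(
        0.18 + 0.45 * ring + 0.18 * (1.0 - base) + speckle * speckle_noise,
        0.0,
        None,
    )
    # per-tile nuisance: independent stain intensity / section thickness variation
    scale_nuc = rng.uniform(0.7, 1.3)
    scale_cyto = rng.uniform(0.7, 1.3)
    od = (
        scale_nuc * nuc[..., None] * stain_matrix[0][None, None, :]
        + scale_cyto * cyto[..., None] * stain_matrix[1][None, None, :]
    )
    rgb = np.exp(-od)
    # per-tile gamma nuisance: corrupts intensity histograms across tiles while
    # leaving the spatial arrangement of the texture intact
    rgb = rgb ** rng.uniform(*gamma_range)
    return np.clip(rgb.transpose(2, 0, 1), 0.0, 1.0)


def generate_dataset(spec: SynthSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Balanced two-class dataset: (images (n, 3, S, S) in [0,1], labels (n,)).

    Label 0 is the benign-like class, label 1 the malignant-like class.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    stain = np.asarray(spec.stain_matrix, dtype=np.float64)
    per_class = [
        dict(
            beta=spec.beta_benign,
            count_range=spec.blob_count_benign,
            radius_range=spec.blob_radius_benign,
            ecc_range=spec.blob_eccentricity_benign,
            speckle=spec.speckle_benign,
            roughness=spec.roughness_benign,
            gamma_range=spec.gamma_range,
        ),
        dict(
            beta=spec.beta_malignant,
            count_range=spec.blob_count_malignant,
            radius_range=spec.blob_radius_malignant,
            ecc_range=spec.blob_eccentricity_malignant,
            speckle=spec.speckle_malignant,
            roughness=spec.roughness_malignant,
            gamma_range=spec.gamma_range,
        ),
    ]
    images, labels = [], []
    for label, kw in enumerate(per_class):
        for _ in range(spec.n_per_class):
            images.append(_render_tile(spec.image_size, stain_matrix=stain, rng=rng, **kw))
            labels.append(label)
    images = np.stack(images)
    labels = np.asarray(labels, dtype=np.int64)
    order = np.random.default_rng(spec.seed + 1).permutation(labels.size)
    return images[order], labels[order]


def luma(image: np.ndarray) -> np.ndarray:
    """Rec. 601 luma of a channel-first RGB image."""
    return 0.299 * image[0] + 0.587 * image[1] + 0.114 * image[2]


def high_freq_fraction(image: np.ndarray) -> float:
    """Fraction of (non-DC) luma spectral power in the top half of radial frequency."""
    y = luma(image)
    power = np.abs(np.fft.fft2(y)) ** 2
    f = np.fft.fftfreq(y.shape[0])
    r = np.sqrt(f[None, :] ** 2 + f[:, None] ** 2)
    total = power[r > 0].sum()
    if total == 0:
        return 0.0
    return float(power[r >= 0.25].sum() / total)


def save_dataset(
    out_dir: str,
    images: np.ndarray,
    labels: np.ndarray,
    class_names: Sequence[str] = ("benign", "malignant"),
) -> None:
    """Write PNG tiles into class-named subdirectories plus a labels.csv manifest."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, (img, lab) in enumerate(zip(images, labels)):
        cls = class_names[int(lab)]
        cls_dir = os.path.join(out_dir, cls)
        os.makedirs(cls_dir, exist_ok=True)
        name = f"tile_{i:05d}.png"
        arr = np.clip(img.transpose(1, 2, 0) * 255.0, 0, 255).round().astype(np.uint8)
        Image.fromarray(arr).save(os.path.join(cls_dir, name))
        rows.append((os.path.join(cls, name), cls, int(lab)))
    with open(os.path.join(out_dir, "labels.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "class", "label"])
        writer.writerows(rows)


def load_image_dataset(
    data_dir: str, image_size: int | None = None
) -> Tuple[np.ndarray, np.ndarray, list]:
    """Load a class-per-subdirectory image tree; returns (images, labels, class_names).

    Class names are the sorted subdirectory names; images are resized to
    ``image_size`` when given.
    """
    classes = sorted(
        d for d in os.listdir(data_dir)
        if os.path.isdir(os.path.join(data_dir, d))
    )
    if not classes:
        raise FileNotFoundError(f"no class subdirectories under {data_dir}")
    images, labels = [], []
    for lab, cls in enumerate(classes):
        cls_dir = os.path.join(data_dir, cls)
        for name in sorted(os.listdir(cls_dir)):
            if not name.lower().endswith((".png", ".jpg", ".jpeg", ".tif", ".tiff")):
                continue
            with Image.open(os.path.join(cls_dir, name)) as im:
                im = im.convert("RGB")
                if image_size is not None and im.size != (image_size, image_size):
                    im = im.resize((image_size, image_size), Image.BILINEAR)
                arr = np.asarray(im, dtype=np.float64) / 255.0
            images.append(arr.transpose(2, 0, 1))
            labels.append(lab)
    return np.stack(images), np.asarray(labels, dtype=np.int64), classes
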