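"""Handcrafted descriptor families used as comparison feature extractors:
colour histogram, luminance histogram, HOG, uniform LBP, and GLCM statistics.

Parameters are fixed, documented defaults; vector lengths are deterministic
functions of the parameters (see ``descriptor_length``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from skimage.feature import graycomatrix, graycoprops, hog, local_binary_pattern
from skimage.transform import resize

__all__ = ["DescriptorSpec", "FAMILIES", "extract_descriptor", "descriptor_length"]

FAMILIES = ("color_histogram", "luminance_histogram", "hog", "lbp", "glcm")

_GLCM_PROPS = ("contrast", "correlation", "energy", "homogeneity", "dissimilarity")


@dataclass
class DescriptorSpec:
    family: str
    color_bins: int = 32
    luma_bins: int = 64
    hog_orientations: int = 9
    hog_cell: int = 8
    hog_block: int = 2
    lbp_radius: int = 1
    lbp_points: int = 8
    glcm_levels: int = 32
    glcm_distances: Tuple[int, ...] = (1,)
    glcm_angles: Tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    image_size: int = 224

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")


def descriptor_length(spec: DescriptorSpec) -> int:
    if spec.family == "color_histogram":
        return 3 * spec.color_bins
    if spec.family == "luminance_histogram":
        return spec.luma_bins
    if spec.family == "hog":
        cells = spec.image_size // spec.hog_cell
        blocks = cells - spec.hog_block + 1
        return blocks * blocks * spec.hog_block * spec.hog_block * spec.hog_orientations
    if spec.family == "lbp":
        return spec.lbp_points + 2  # uniform patterns + the non-uniform bin
    if spec.family == "glcm":
        return len(_GLCM_PROPS)
    raise ValueError(spec.family)


def _luma(image_hwc: np.ndarray) -> np.ndarray:
    return image_hwc @ np.array([0.299, 0.587, 0.114])


def _prepare(image: np.ndarray, spec: DescriptorSpec) -> np.ndarray:
    """Channel-first or channel-last RGB in [0,1] -> HWC resized to the spec size."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3:
        raise ValueError(f"expected an RGB image, got shape {image.shape}")
    if image.shape[0] == 3 and image.shape[-1] != 3:
        image = image.transpose(1, 2, 0)
    if image.shape[-1] != 3:
        raise ValueError(f"expected 3 colour channels, got shape {image.shape}")
    s = spec.image_size
    if image.shape[:2] != (s, s):
        image = resize(image, (s, s), order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True)
    return np.clip(image, 0.0, 1.0)


def extract_descriptor(image: np.ndarray, spec: DescriptorSpec) -> np.ndarray:
    """Fixed-length descriptor for one RGB tile.

    * ``color_histogram``: per-channel histogram, each channel normalized to
      unit mass (so the full vector sums to 3).
    * ``luminance_histogram``: normalized histogram of Rec. 601 luma.
    * ``hog``: orientation histograms on the grayscale image.
    * ``lbp``: normalized histogram of uniform local binary patterns.
    * ``glcm``: contrast / correlation / energy / homogeneity / dissimilarity
      of the gray co-occurrence matrix, averaged over angles.
    """
    hwc = _prepare(image, spec)
    if spec.family == "color_histogram":
        parts = []
        for c in range(3):
            counts, _ = np.histogram(hwc[..., c], bins=spec.color_bins, range=(0, 1))
            total = counts.sum()
            parts.append(counts / total if total else counts.astype(float))
        return np.concatenate(parts)
    gray = _luma(hwc)
    if spec.family == "luminance_histogram":
        counts, _ = np.histogram(gray, bins=spec.luma_bins, range=(0, 1))
        total = counts.sum()
        return counts / total if total else counts.astype(float)
    if spec.family == "hog":
        return hog(
            gray,
            orientations=spec.hog_orientations,
            pixels_per_cell=(spec.hog_cell, spec.hog_cell),
            cells_per_block=(spec.hog_block, spec.hog_block),
            block_norm="L2-Hys",
            feature_vector=True,
        )
    if spec.family == "lbp":
        import warnings

        with warnings.catch_warnings():
            # float input is intentional; values are quantization-free in [0,1]
            warnings.filterwarnings("ignore", message=".*floating-point images.*")
            codes = local_binary_pattern(gray, P=spec.lbp_points, R=spec.lbp_radius,
                                         method="uniform")
        n_bins = spec.lbp_points + 2
        counts, _ = np.histogram(codes, bins=n_bins, range=(0, n_bins))
        return counts / counts.sum()
    if spec.family == "glcm":
        levels = spec.glcm_levels
        quant = np.clip((gray * levels).astype(np.int64), 0, levels - 1)
        glcm = graycomatrix(
            quant.astype(np.uint8),
            distances=list(spec.glcm_distances),
            angles=list(spec.glcm_angles),
            levels=levels,
            symmetric=True,
            normed=True,
        )
        return np.array([
            float(graycoprops(glcm, prop).mean()) for prop in _GLCM_PROPS
        ])
    raise ValueError(spec.family)


def extract_features(images: np.ndarray, spec: DescriptorSpec) -> np.ndarray:
    """Stack of descriptors for a batch of channel-first images."""
    return np.stack([extract_descriptor(img, spec) for img in images])
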