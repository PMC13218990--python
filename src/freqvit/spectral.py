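"""Spectral refinement primitives: patch-grid relayout, 2-D Fourier pair, and
the squeeze-and-excitation channel gate applied in the frequency domain.

Conventions
-----------
* The full complex transform is used (``numpy.fft.fft2``), so a spectrum of a
  ``D x Hp x Wp`` grid has shape ``D x Hp x Wp`` with the zero-frequency
  coefficient at index ``(0, 0)``.  The half-spectrum real-input transform is
  an equivalent alternative; the full transform is kept because its adjoint is
  its (scaled) inverse, which the hand-written backward pass relies on.
* Normalization: unnormalized forward, ``1/(Hp*Wp)`` inverse.  A constant grid
  ``c`` therefore has a single nonzero coefficient ``c*Hp*Wp`` at the origin.
* The channel descriptor feeding the gate is the mean magnitude of the
  spectrum -- phase-invariant and absolutely homogeneous of degree one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "SEParams",
    "to_patch_grid",
    "from_patch_grid",
    "fft2",
    "ifft2",
    "spectrum_descriptor",
    "se_gate",
    "apply_gate",
    "spectral_refine",
]

_IMAG_TOL = 1e-5


@dataclass
class SEParams:
    """Two affine maps of the squeeze-and-excitation bottleneck (D -> D/r -> D)."""

    w1: np.ndarray  # (D, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden, D)
    b2: np.ndarray  # (D,)

    def __post_init__(self) -> None:
        d, hidden = self.w1.shape
        if self.w2.shape != (hidden, d):
            raise ValueError(
                f"w2 shape {self.w2.shape} inconsistent with w1 shape {self.w1.shape}"
            )
        if self.b1.shape != (hidden,) or self.b2.shape != (d,):
            raise ValueError("bias shapes inconsistent with weight shapes")

    @classmethod
    def zeros(cls, dim: int, reduction: int) -> "SEParams":
        hidden = max(1, dim // reduction)
        return cls(
            w1=np.zeros((dim, hidden)),
            b1=np.zeros(hidden),
            w2=np.zeros((hidden, dim)),
            b2=np.zeros(dim),
        )


def to_patch_grid(tokens: np.ndarray, grid_shape: Tuple[int, int]) -> np.ndarray:
    """Re-layout ``N x D`` patch tokens as a channel-first ``D x Hp x Wp`` grid.

    Token row ``k`` maps to grid cell ``(k // Wp, k % Wp)`` (row-major).
    """
    hp, wp = grid_shape
    tokens = np.asarray(tokens)
    if tokens.ndim != 2:
        raise ValueError(f"expected 2-D token matrix, got shape {tokens.shape}")
    n, d = tokens.shape
    if n != hp * wp:
        raise ValueError(f"token count {n} does not match grid {hp}x{wp}")
    return tokens.reshape(hp, wp, d).transpose(2, 0, 1)


def from_patch_grid(grid: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_patch_grid`; bitwise round-trip."""
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise ValueError(f"expected D x Hp x Wp grid, got shape {grid.shape}")
    d, hp, wp = grid.shape
    return grid.transpose(1, 2, 0).reshape(hp * wp, d)


def fft2(grid: np.ndarray) -> np.ndarray:
    """Per-channel 2-D forward transform (unnormalized)."""
    grid = np.asarray(grid)
    if not np.isfinite(grid).all():
        raise ValueError("non-finite values in patch grid")
    return np.fft.fft2(grid, axes=(-2, -1))


def ifft2(spectrum: np.ndarray, grid_shape: Tuple[int, int]) -> np.ndarray:
    """Inverse transform back to a real grid.

    Raises if the imaginary residue exceeds tolerance relative to the grid
    magnitude, which signals a spectrum whose conjugate symmetry was broken.
    """
    spectrum = np.asarray(spectrum)
    if spectrum.shape[-2:] != tuple(grid_shape):
        raise ValueError(
            f"spectrum spatial shape {spectrum.shape[-2:]} != grid_shape {tuple(grid_shape)}"
        )
    out = np.fft.ifft2(spectrum, axes=(-2, -1))
    scale = max(float(np.abs(out.real).max()), 1.0)
    resid = float(np.abs(out.imag).max())
    if resid > _IMAG_TOL * scale:
        raise ValueError(
            f"imaginary residue {resid:.3g} exceeds tolerance; corrupted spectrum"
        )
    return out.real


def spectrum_descriptor(spectrum: np.ndarray) -> np.ndarray:
    """Per-channel mean magnitude over all frequency locations."""
    return np.abs(spectrum).mean(axis=(-2, -1))


def _se_forward(descriptor: np.ndarray, params: SEParams) -> np.ndarray:
    hidden = np.maximum(descriptor @ params.w1 + params.b1, 0.0)
    logits = hidden @ params.w2 + params.b2
    return 1.0 / (1.0 + np.exp(-logits))


def se_gate(spectrum: np.ndarray, params: SEParams) -> np.ndarray:
    """Sigmoid channel gate computed from the spectrum's magnitude summary.

    Returns a vector of length ``D`` with every entry strictly in ``(0, 1)``.
    """
    d = spectrum_descriptor(spectrum)
    if d.shape[-1] != params.w1.shape[0]:
        raise ValueError(
            f"channel count {d.shape[-1]} does not match SE input dim {params.w1.shape[0]}"
        )
    return _se_forward(d, params)


def apply_gate(spectrum: np.ndarray, gate: np.ndarray) -> np.ndarray:
    """Scale channel ``c`` of the spectrum by the real scalar ``gate[c]``."""
    spectrum = np.asarray(spectrum)
    gate = np.asarray(gate)
    if gate.shape[-1] != spectrum.shape[-3]:
        raise ValueError(
            f"gate length {gate.shape[-1]} does not match channel count {spectrum.shape[-3]}"
        )
    return spectrum * gate[..., :, None, None]


def spectral_refine(
    patch_tokens: np.ndarray,
    grid_shape: Tuple[int, int],
    se_params: SEParams | None,
    spectral_filter: np.ndarray | None = None,
) -> np.ndarray:
    """The full frequency-domain branch on (already normalized) patch tokens.

    ``FFT -> [optional learned filter] -> [optional SE gate] -> IFFT``,
    returned in token layout.  With ``se_params=None`` and no filter this is
    the round-trip identity up to floating-point error.
    """
    grid = to_patch_grid(patch_tokens, grid_shape)
    spec = fft2(grid)
    if spectral_filter is not None:
        spec = spec * spectral_filter
    if se_params is not None:
        gate = se_gate(spec, se_params)
        spec = apply_gate(spec, gate)
    out = ifft2(spec, grid_shape)
    return from_patch_grid(out)
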