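import numpy as np
import pytest

from freqvit import spectral
from freqvit.spectral import (
    SEParams,
    apply_gate,
    fft2,
    from_patch_grid,
    ifft2,
    se_gate,
    spectral_refine,
    spectrum_descriptor,
    to_patch_grid,
)


def dense_dft_matrix(n):
    """Explicit 1-D DFT matrix, the independent dense-transform oracle."""
    j, k = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return np.exp(-2j * np.pi * j * k / n)


class TestPatchGridLayout:
    def test_round_trip_bitwise(self, rng):
        tokens = rng.normal(size=(196, 8))
        grid = to_patch_grid(tokens, (14, 14))
        assert grid.shape == (8, 14, 14)
        back = from_patch_grid(grid)
        assert np.array_equal(back, tokens)

    def test_row_major_index_mapping(self, rng):
        tokens = rng.normal(size=(12, 3))
        grid = to_patch_grid(tokens, (3, 4))
        for k in range(12):
            assert np.array_equal(grid[:, k // 4, k % 4], tokens[k])

    def test_2x2_transpose_differs(self):
        # explicit enumeration: rows [0,1,2,3] -> grid [[0,1],[2,3]]
        tokens = np.arange(4, dtype=float).reshape(4, 1)
        grid = to_patch_grid(tokens, (2, 2))
        expected = np.array([[[0.0, 1.0], [2.0, 3.0]]])
        assert np.array_equal(grid, expected)
        assert not np.array_equal(grid[0].T, grid[0])

    def test_count_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="does not match"):
            to_patch_grid(rng.normal(size=(5, 2)), (2, 2))


class TestFourierPair:
    def test_round_trip(self, rng):
        grid = rng.normal(size=(6, 8, 8))
        back = ifft2(fft2(grid), (8, 8))
        assert np.abs(back - grid).max() < 1e-5

    def test_constant_grid_dc_only(self):
        c = 2.5
        grid = np.full((3, 4, 4), c)
        spec = fft2(grid)
        assert np.allclose(spec[:, 0, 0], c * 16)
        mask = np.ones((4, 4), dtype=bool)
        mask[0, 0] = False
        assert np.abs(spec[:, mask]).max() < 1e-9

    def test_coefficients_match_dense_oracle(self, rng):
        grid = rng.normal(size=(2, 4, 4))
        f = dense_dft_matrix(4)
        expected = np.einsum("jm,cmn,kn->cjk", f, grid, f)
        assert np.allclose(fft2(grid), expected, atol=1e-10)

    def test_parseval_vs_dense_oracle(self, rng):
        grid = rng.normal(size=(2, 4, 4))
        spec = fft2(grid)
        energy_spatial = (grid**2).sum()
        energy_spectral = (np.abs(spec) ** 2).sum() / 16
        assert np.isclose(energy_spatial, energy_spectral, rtol=1e-10)

    def test_imag_residue_rejected(self, rng):
        spec = fft2(rng.normal(size=(1, 4, 4))).astype(complex)
        spec[0, 1, 1] += 100.0j  # break conjugate symmetry
        with pytest.raises(ValueError, match="imaginary residue"):
            ifft2(spec, (4, 4))

    def test_nonfinite_rejected(self):
        grid = np.ones((1, 4, 4))
        grid[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fft2(grid)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="grid_shape"):
            ifft2(fft2(rng.normal(size=(1, 4, 4))), (8, 8))


class TestSEGate:
    def test_zero_weights_give_half(self, rng):
        spec = fft2(rng.normal(size=(8, 4, 4)))
        gate = se_gate(spec, SEParams.zeros(8, 2))
        assert np.allclose(gate, 0.5)

    def test_bounds(self, rng):
        params = SEParams(
            w1=rng.normal(size=(8, 2)),
            b1=rng.normal(size=2),
            w2=rng.normal(size=(2, 8)),
            b2=rng.normal(size=8),
        )
        gate = se_gate(fft2(rng.normal(size=(8, 4, 4))), params)
        assert gate.shape == (8,)
        assert ((gate > 0) & (gate < 1)).all()

    def test_descriptor_translation_invariant(self, rng):
        grid = rng.normal(size=(5, 8, 8))
        d0 = spectrum_descriptor(fft2(grid))
        d1 = spectrum_descriptor(fft2(np.roll(grid, shift=(3, 5), axis=(1, 2))))
        assert np.abs(d0 - d1).max() < 1e-5

    def test_descriptor_homogeneous(self, rng):
        grid = rng.normal(size=(3, 8, 8))
        d = spectrum_descriptor(fft2(grid))
        assert np.allclose(spectrum_descriptor(fft2(2.0 * grid)), 2.0 * d)

    def test_bad_param_shapes(self):
        with pytest.raises(ValueError):
            SEParams(
                w1=np.zeros((8, 2)), b1=np.zeros(2),
                w2=np.zeros((3, 8)), b2=np.zeros(8),
            )


class TestApplyGate:
    def test_ones_identity(self, rng):
        spec = fft2(rng.normal(size=(4, 4, 4)))
        assert np.array_equal(apply_gate(spec, np.ones(4)), spec)

    def test_zeros_give_zero_grid(self, rng):
        spec = fft2(rng.normal(size=(4, 4, 4)))
        out = ifft2(apply_gate(spec, np.zeros(4)), (4, 4))
        assert np.abs(out).max() == 0.0

    def test_gate_commutes_with_inverse_transform(self, rng):
        # gate then ifft2 == ifft2 then per-channel spatial scaling
        grid = rng.normal(size=(6, 8, 8))
        gate = rng.uniform(0.1, 0.9, size=6)
        via_spectrum = ifft2(apply_gate(fft2(grid), gate), (8, 8))
        via_spatial = grid * gate[:, None, None]
        assert np.abs(via_spectrum - via_spatial).max() < 1e-5

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError, match="gate length"):
            apply_gate(fft2(rng.normal(size=(4, 4, 4))), np.ones(3))


class TestSpectralRefine:
    def test_identity_without_gate(self, rng):
        tokens = rng.normal(size=(16, 5))
        out = spectral_refine(tokens, (4, 4), se_params=None)
        assert np.abs(out - tokens).max() < 1e-10

    def test_gated_output_real_and_bounded(self, rng):
        params = SEParams(
            w1=rng.normal(size=(5, 2)), b1=rng.normal(size=2),
            w2=rng.normal(size=(2, 5)), b2=rng.normal(size=5),
        )
        tokens = rng.normal(size=(16, 5))
        out = spectral_refine(tokens, (4, 4), se_params=params)
        assert out.shape == tokens.shape
        assert np.isfinite(out).all()
        # per-channel real scaling preserves conjugate symmetry => |out| <= |in| scale-wise
        gate = se_gate(fft2(to_patch_grid(tokens, (4, 4))), params)
        expected = tokens * gate[None, :]
        assert np.abs(out - expected).max() < 1e-5

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_randomized_round_trip_property(self, seed):
        rng = np.random.default_rng(seed)
        hp, wp = int(rng.integers(2, 9)), int(rng.integers(2, 9))
        d = int(rng.integers(1, 7))
        grid = rng.normal(size=(d, hp, wp)) * 10.0 ** float(rng.integers(-2, 3))
        back = ifft2(fft2(grid), (hp, wp))
        scale = max(np.abs(grid).max(), 1.0)
        assert np.abs(back - grid).max() < 1e-5 * scale
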