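"""Mask construction, zero-fill padding, and masked-FFT reconstruction."""

import numpy as np
import pytest

from diagqm import (
    ImageVolume,
    KSpaceMask,
    MaskConfig,
    make_undersampling_mask,
    pad_mask_for_zero_fill,
    undersample_volume,
)
from diagqm.kspace import central_band


class TestMaskConstruction:
    def test_r4_512_lines_samples_quarter_with_20pct_central_band(self):
        mask = make_undersampling_mask(512, MaskConfig(acceleration=4.0, seed=0))
        assert mask.n_sampled == 128  # 25% of k-space
        band = central_band(512, 26)  # 20% of 128 samples, rounded
        assert set(band) <= set(mask.sampled_lines)
        assert len(band) == 26

    def test_r1_samples_all_lines(self):
        mask = make_undersampling_mask(512, MaskConfig(acceleration=1.0))
        assert mask.sampled_lines == tuple(range(512))

    @pytest.mark.parametrize("n_lines", [64, 96, 511])
    def test_budget_and_uniqueness(self, n_lines):
        mask = make_undersampling_mask(n_lines, MaskConfig(acceleration=8.0, seed=3))
        assert mask.n_sampled == round(n_lines / 8)
        assert len(set(mask.sampled_lines)) == mask.n_sampled
        assert all(0 <= i < n_lines for i in mask.sampled_lines)

    def test_central_band_tie_break_extra_line_on_positive_side(self):
        # even count: one more line above DC than below
        band = central_band(100, 4)
        dc = 50
        assert band == (49, 50, 51, 52)
        assert sum(i > dc for i in band) == 2
        assert sum(i < dc for i in band) == 1

    def test_determinism_and_seed_sensitivity(self):
        cfg = MaskConfig(acceleration=4.0, seed=42)
        m1 = make_undersampling_mask(256, cfg)
        m2 = make_undersampling_mask(256, cfg)
        m3 = make_undersampling_mask(256, MaskConfig(acceleration=4.0, seed=43))
        assert m1.sampled_lines == m2.sampled_lines
        assert m1.sampled_lines != m3.sampled_lines

    def test_excessive_acceleration_rejected(self):
        with pytest.raises(ValueError):
            make_undersampling_mask(16, MaskConfig(acceleration=16.0))

    def test_peripheral_density_decays_with_distance_from_centre(self):
        """Monte-Carlo frequency oracle: empirical sampling frequency of
        peripheral lines decays monotonically over distance deciles."""
        n_lines, n_seeds = 128, 2000
        counts = np.zeros(n_lines)
        central = set(central_band(n_lines, round(0.2 * round(n_lines / 8))))
        for seed in range(n_seeds):
            m = make_undersampling_mask(
                n_lines, MaskConfig(acceleration=8.0, seed=seed)
            )
            counts[list(m.sampled_lines)] += 1
        dc = n_lines // 2
        peripheral = np.array([i for i in range(n_lines) if i not in central])
        dist = np.abs(peripheral - dc)
        freq = counts[peripheral] / n_seeds
        deciles = np.quantile(dist, np.linspace(0, 1, 11))
        means = [
            freq[(dist >= deciles[k]) & (dist < deciles[k + 1])].mean()
            for k in range(10)
        ]
        assert all(a > b for a, b in zip(means[:-1], means[1:]))

    def test_mask_json_round_trip(self):
        mask = make_undersampling_mask(96, MaskConfig(acceleration=4.0, seed=9))
        assert KSpaceMask.from_json(mask.to_json()) == mask


class TestZeroFillPadding:
    def test_pad_256_to_512_outer_quarters_unsampled(self):
        mask = make_undersampling_mask(256, MaskConfig(acceleration=4.0, seed=0))
        padded = pad_mask_for_zero_fill(mask, 256, 512)
        arr = padded.as_array()
        assert padded.n_lines == 512
        assert not arr[:128].any() and not arr[384:].any()
        assert np.array_equal(arr[128:384], mask.as_array())

    def test_identity_when_sizes_match(self):
        mask = make_undersampling_mask(128, MaskConfig(acceleration=4.0, seed=1))
        assert pad_mask_for_zero_fill(mask, 128, 128).sampled_lines == mask.sampled_lines

    def test_padding_preserves_sample_count_and_rejects_shrink(self):
        mask = make_undersampling_mask(128, MaskConfig(acceleration=4.0, seed=1))
        assert pad_mask_for_zero_fill(mask, 128, 300).n_sampled == mask.n_sampled
        with pytest.raises(ValueError):
            pad_mask_for_zero_fill(mask, 128, 100)


def _dft_oracle(slice2d: np.ndarray, sampled: set[int], axis: int) -> np.ndarray:
    """Explicit-summation masked DFT reconstruction (O(N^4) per slice)."""
    n, m = slice2d.shape
    ksp = np.zeros((n, m), dtype=complex)
    for u in range(n):
        for v in range(m):
            for i in range(n):
                for j in range(m):
                    ksp[u, v] += slice2d[i, j] * np.exp(-2j * np.pi * (u * i / n + v * j / m))
    ksp = np.fft.fftshift(ksp)
    for idx in range(ksp.shape[axis]):
        if idx not in sampled:
            if axis == 0:
                ksp[idx, :] = 0
            else:
                ksp[:, idx] = 0
    ksp = np.fft.ifftshift(ksp)
    out = np.zeros((n, m), dtype=complex)
    for i in range(n):
        for j in range(m):
            for u in range(n):
                for v in range(m):
                    out[i, j] += ksp[u, v] * np.exp(2j * np.pi * (u * i / n + v * j / m))
    return np.abs(out) / (n * m)


class TestUndersampling:
    def test_full_sampling_round_trip(self, ramp_volume):
        mask = make_undersampling_mask(16, MaskConfig(acceleration=1.0))
        out = undersample_volume(ramp_volume, mask)
        rng = ramp_volume.data.max() - ramp_volume.data.min()
        assert np.abs(out.data - ramp_volume.data).max() < 1e-6 * rng

    def test_constant_slice_survives_any_mask_with_dc(self):
        vol = ImageVolume(np.full((32, 32, 1), 0.7))
        mask = make_undersampling_mask(32, MaskConfig(acceleration=4.0, seed=5))
        out = undersample_volume(vol, mask)
        assert np.allclose(out.data, 0.7, atol=1e-9)

    def test_matches_explicit_dft_oracle_on_16x16_ramp(self):
        x, y = np.meshgrid(np.linspace(0, 1, 16), np.linspace(0, 1, 16), indexing="ij")
        slice2d = 0.1 + 0.8 * x + 0.1 * y
        vol = ImageVolume(slice2d[:, :, None])
        mask = make_undersampling_mask(16, MaskConfig(acceleration=4.0, seed=7))
        ours = undersample_volume(vol, mask).data[:, :, 0]
        oracle = _dft_oracle(slice2d, set(mask.sampled_lines), axis=0)
        assert np.abs(ours - oracle).max() < 1e-8

    def test_energy_non_increase(self, rng):
        vol = ImageVolume(rng.random((32, 32, 2)))
        full = np.sum(np.abs(np.fft.fft2(vol.data[:, :, 0])) ** 2)
        mask = make_undersampling_mask(32, MaskConfig(acceleration=4.0, seed=1))
        ksp = np.fft.fftshift(np.fft.fft2(vol.data[:, :, 0]))
        masked = ksp * mask.as_array()[:, None]
        assert np.sum(np.abs(masked) ** 2) < full
        full_mask = make_undersampling_mask(32, MaskConfig(acceleration=1.0))
        masked1 = ksp * full_mask.as_array()[:, None]
        assert np.isclose(np.sum(np.abs(masked1) ** 2), full)

    def test_resolution_lost_only_along_phase_encoding_axis(self, rng):
        """Profiles orthogonal to the undersampled axis are preserved: a
        pattern varying only along the frequency-encoding axis passes
        through any mask that includes the DC line."""
        pattern = np.tile(rng.random(32)[None, :], (32, 1))
        vol = ImageVolume(pattern[:, :, None])
        mask = make_undersampling_mask(32, MaskConfig(acceleration=4.0, seed=2, axis=0))
        out = undersample_volume(vol, mask).data[:, :, 0]
        assert np.abs(out - pattern).max() < 1e-9

    def test_shape_mismatch_rejected(self, ramp_volume):
        mask = make_undersampling_mask(32, MaskConfig(acceleration=2.0))
        with pytest.raises(ValueError):
            undersample_volume(ramp_volume, mask)

    def test_ssim_ordering_r8_below_r4(self, small_cohort):
        """Stronger acceleration degrades structural similarity more."""
        from diagqm import ssim

        deltas = []
        for i, case in enumerate(small_cohort[:6]):
            n = case.image.shape[0]
            v4 = undersample_volume(
                case.image, make_undersampling_mask(n, MaskConfig(4.0, seed=i))
            )
            v8 = undersample_volume(
                case.image, make_undersampling_mask(n, MaskConfig(8.0, seed=i))
            )
            deltas.append(ssim(case.image, v4) - ssim(case.image, v8))
        assert np.mean(deltas) > 0
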