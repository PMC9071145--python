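"""Filter-bank decomposition, thresholding, reconstruction, T optimisation."""

import numpy as np
import pytest

import perceptqa as pq
from perceptqa.denoise import Decomposition, ThresholdPolicy


class TestBankGeometry:
    @pytest.mark.parametrize("fwhh,expected", [(45.0, 4), (22.5, 8), (11.25, 16)])
    def test_orientation_count(self, fwhh, expected):
        cfg = pq.FilterBankConfig(size=64, orient_fwhh=fwhh, n_scales=3)
        assert cfg.n_orientations == expected

    def test_octave_scale_ladder(self):
        cfg = pq.FilterBankConfig(size=256, n_scales=6, base_f0=64.0)
        assert cfg.scale_f0s == (64, 32, 16, 8, 4, 2)

    def test_rejects_f0_at_or_above_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            pq.FilterBank(pq.FilterBankConfig(size=64, base_f0=40.0, n_scales=3))

    def test_rejects_grid_size_mismatch(self, grid128):
        with pytest.raises(ValueError, match="size"):
            pq.FilterBank(pq.FilterBankConfig(size=64, n_scales=3), grid128)

    def test_coverage_bounded_below(self, bank128):
        # non-DC squared-amplitude sum well away from zero
        D = bank128._D
        assert min(D[1:, :].min(), D[0, 1:].min()) > 1e-3


class TestRoundTrip:
    @pytest.mark.parametrize("family", ["cartesian", "polar"])
    @pytest.mark.parametrize("fwhh", [11.25, 22.5, 45.0])
    def test_unthresholded_reconstruction(self, family, fwhh):
        bank = pq.FilterBank(pq.FilterBankConfig(
            size=128, n_scales=5, orient_fwhh=fwhh, family=family))
        for seed in range(4):
            im = pq.synth_natural_image(128, -1.45, 21.0, seed=100 + seed)
            rec = bank.reconstruct(bank.decompose(im))
            rel = np.sqrt(np.mean((rec - im.pixels) ** 2)) / im.pixels.std()
            assert rel < 1e-3

    def test_decomposition_bank_mismatch(self, bank128, images128):
        other = pq.FilterBank(pq.FilterBankConfig(size=128, n_scales=4))
        dec = bank128.decompose(images128[0])
        with pytest.raises(ValueError, match="different bank"):
            other.reconstruct(dec)

    def test_image_size_mismatch(self, bank128):
        with pytest.raises(ValueError, match="shape"):
            bank128.decompose(np.zeros((64, 64)))


class TestDecompose:
    def test_matched_grating_drives_its_filter_hardest(self, bank128):
        spec = bank128.specs[bank128.element_labels.index((1, 2))]
        yy, xx = np.mgrid[0:128, 0:128]
        th = np.radians(spec.theta0)
        phase = 2 * np.pi * spec.f0 * (xx * np.cos(th) + yy * np.sin(th)) / 128
        grating = 0.5 + 0.2 * np.cos(phase)
        dec = bank128.decompose(grating)
        energies = [float(np.abs(c).max()) for c in dec.coeffs]
        assert int(np.argmax(energies)) == bank128.element_labels.index((1, 2))

    def test_constant_image_gives_zero_coefficients(self, bank128):
        dec = bank128.decompose(np.full((128, 128), 0.5))
        for c in dec.coeffs:
            assert np.abs(c).max() < 1e-12
        assert dec.lowpass == pytest.approx(0.5, abs=1e-12)

    def test_white_noise_energy_grows_with_scale_frequency(self, bank128):
        # oracle: subband noise energy is the Fourier integral of the squared
        # amplitude, i.e. E|c|^2 = sigma^2 * mean(M^2)
        rng = np.random.default_rng(7)
        # average several draws: the coarsest subband has few Fourier samples
        decs = [bank128.decompose(rng.normal(0.5, 0.1, (128, 128)))
                for _ in range(8)]
        per_scale, oracle = [], []
        for s in range(bank128.config.n_scales):
            j = bank128.element_labels.index((s, 0))
            per_scale.append(float(np.mean(
                [np.mean(np.abs(d.coeffs[j]) ** 2) for d in decs])))
            oracle.append(0.1 ** 2 * float(np.mean(bank128.elements[j] ** 2)))
        # finest scale (index 0) has the largest annulus, hence most energy
        assert all(a > b for a, b in zip(per_scale, per_scale[1:]))
        np.testing.assert_allclose(per_scale, oracle, rtol=0.2)


class TestThresholding:
    def _toy_decomposition(self, bank):
        rng = np.random.default_rng(0)
        im = rng.normal(0.5, 0.05, (128, 128))
        return bank.decompose(im)

    def test_zero_threshold_is_identity(self, bank128):
        dec = self._toy_decomposition(bank128)
        out = pq.threshold_coeffs(dec, ThresholdPolicy(T=0.0, mode="hard"), bank128)
        for a, b in zip(dec.coeffs, out.coeffs):
            np.testing.assert_array_equal(a, b)

    def test_huge_hard_threshold_kills_everything(self, bank128):
        dec = self._toy_decomposition(bank128)
        big = max(float(np.abs(c).max()) for c in dec.coeffs) * 1.01
        out = pq.threshold_coeffs(dec, ThresholdPolicy(T=big, mode="hard"), bank128)
        for c in out.coeffs:
            assert np.abs(c).max() == 0.0
        np.testing.assert_array_equal(out.lowpass, dec.lowpass)  # residual untouched

    def test_soft_shrinkage_preserves_phase(self, bank128):
        dec = self._toy_decomposition(bank128)
        T = 0.01
        c0 = dec.coeffs[0]
        out = pq.threshold_coeffs(dec, ThresholdPolicy(T=T, mode="soft"), bank128)
        c1 = out.coeffs[0]
        mag0, mag1 = np.abs(c0), np.abs(c1)
        np.testing.assert_allclose(mag1, np.maximum(mag0 - T, 0.0), atol=1e-12)
        kept = mag1 > 1e-9
        np.testing.assert_allclose(np.angle(c1[kept]), np.angle(c0[kept]), atol=1e-9)

    def test_soft_coefficient_at_twice_threshold_halves(self, bank128):
        c = np.zeros((128, 128), complex)
        c[3, 5] = 0.02 * np.exp(1j * 0.7)
        dec = Decomposition(coeffs=[c] + [np.zeros_like(c)] * (bank128.n_elements - 1),
                            lowpass=np.zeros((128, 128)), bank_key=bank128._key())
        out = pq.threshold_coeffs(dec, ThresholdPolicy(T=0.01, mode="soft"), bank128)
        assert abs(out.coeffs[0][3, 5]) == pytest.approx(0.01)
        assert np.angle(out.coeffs[0][3, 5]) == pytest.approx(0.7)

    def test_zeroing_all_planes_and_residuals_gives_constant(self, bank128, images128):
        dec = bank128.decompose(images128[0])
        zeroed = Decomposition(coeffs=[np.zeros_like(c) for c in dec.coeffs],
                               lowpass=np.zeros_like(dec.lowpass),
                               bank_key=dec.bank_key)
        rec = bank128.reconstruct(zeroed)
        assert np.ptp(rec) < 1e-12

    def test_highfreq_energy_nonincreasing_in_threshold(self, bank128, images128):
        noisy = pq.add_white_noise(images128[0], pq.NoiseCondition(18.0, 5))
        dec = bank128.decompose(noisy)
        fr = np.fft.fftfreq(128) * 128
        f = np.hypot(*np.meshgrid(fr, fr))
        energies = []
        for t in [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]:
            policy = ThresholdPolicy.noise_scaled(t, 18.0) if t else ThresholdPolicy(T=0.0)
            rec = bank128.reconstruct(pq.threshold_coeffs(dec, policy, bank128))
            X = np.abs(np.fft.fft2(rec - rec.mean())) ** 2
            energies.append(float(X[f > 32].sum()))
        assert all(a >= b - 1e-9 for a, b in zip(energies, energies[1:]))

    def test_scales_restriction_leaves_other_scales_alone(self, bank128):
        dec = self._toy_decomposition(bank128)
        policy = ThresholdPolicy(T=1.0, mode="hard", scales=(0,))
        out = pq.threshold_coeffs(dec, policy, bank128)
        for j, lab in enumerate(bank128.element_labels):
            scale = bank128.element_scale(j)
            if scale not in (0, None):
                np.testing.assert_array_equal(out.coeffs[j], dec.coeffs[j])


class TestDenoise:
    def test_zero_policy_round_trips(self, bank128, images128):
        im = images128[0]
        out = pq.denoise(im, bank128, ThresholdPolicy(T=0.0))
        assert np.sqrt(np.mean((out - im.pixels) ** 2)) < 1e-6

    def test_improves_psnr_at_high_noise(self, bank128, images128):
        level = 22.0
        gains = []
        for i, im in enumerate(images128[:3]):
            noisy = pq.add_white_noise(im, pq.NoiseCondition(level, 50 + i))
            den = pq.denoise(noisy.pixels, bank128,
                             ThresholdPolicy.noise_scaled(3.0, level))
            gains.append(pq.psnr(im, den) - pq.psnr(im, noisy))
        assert np.mean(gains) > 1.0

    def test_output_in_unit_interval(self, bank128, images128):
        noisy = pq.add_white_noise(images128[0], pq.NoiseCondition(27.0, 9))
        out = pq.denoise(noisy.pixels, bank128, ThresholdPolicy.noise_scaled(3.0, 27.0))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_family_equivalence_within_1db(self, images128):
        level = 18.0
        means = {}
        for family in ("cartesian", "polar"):
            bank = pq.FilterBank(pq.FilterBankConfig(size=128, n_scales=5,
                                                     orient_fwhh=22.5, family=family))
            opt = pq.optimize_threshold(images128[:4], level, bank, seed=3)
            means[family] = opt.mean_psnr
        assert abs(means["cartesian"] - means["polar"]) < 1.0


class TestOptimizeThreshold:
    def test_polyfit_matches_dense_grid_search(self, bank128, images128):
        level = 18.0
        coarse = np.geomspace(0.7, 5.6, 9)
        opt = pq.optimize_threshold(images128[:2], level, bank128,
                                    t_grid=coarse, seed=3)
        dense = np.geomspace(0.7, 5.6, 33)
        dense_opt = pq.optimize_threshold(images128[:2], level, bank128,
                                          t_grid=dense, degree=8, seed=3)
        # within one coarse-grid step (log spacing factor)
        step = coarse[1] / coarse[0]
        ratio = opt.t_star / dense_opt.t_star
        assert 1 / step <= ratio <= step

    def test_monotone_grid_returns_boundary(self, bank128, images128):
        # beyond the optimum the PSNR decreases with t: argmax at the boundary
        grid = np.geomspace(4.0, 32.0, 9)
        opt = pq.optimize_threshold(images128[:2], 24.0, bank128, t_grid=grid, seed=3)
        assert opt.t_star <= grid[1]

    def test_mean_psnr_at_tstar_not_worse_than_grid(self, bank128, images128):
        opt = pq.optimize_threshold(images128[:2], 18.0, bank128, seed=3)
        assert opt.mean_psnr >= max(opt.grid_mean_psnr) - 0.2

    def test_rejects_tiny_grid(self, bank128, images128):
        with pytest.raises(ValueError, match="5"):
            pq.optimize_threshold(images128[:2], 18.0, bank128, t_grid=[1, 2, 3])
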