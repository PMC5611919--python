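"""k-space resampling, dispersion handling, FFT reconstruction,
surface detection and en-face projection."""

import math

import numpy as np
import pytest

import visocm as v
from visocm import phantoms
from visocm.reconstruct import (
    SurfaceMap,
    Tomogram,
    peak_fwhm,
    resample_to_k,
    slab_pixel_range,
    wavelength_to_k,
)


class TestResampleToK:
    lam = np.linspace(425.0, 685.0, 512)

    def test_constant_spectrum_stays_constant(self):
        k, out = resample_to_k(np.full(512, 3.7), self.lam)
        np.testing.assert_allclose(out, 3.7, rtol=1e-9)

    def test_identity_when_already_uniform_in_k(self):
        k_in = np.linspace(wavelength_to_k(685.0), wavelength_to_k(425.0), 512)
        lam_of_k = 2.0e3 * math.pi / k_in
        y = np.exp(-(((lam_of_k - 555) / 80.0) ** 2))
        # wavelengths presented in the calibration's (descending) order
        k, out = resample_to_k(y[::-1], lam_of_k[::-1])
        np.testing.assert_allclose(out, y, rtol=1e-6)

    def test_fringe_peak_matches_nudft(self):
        z = 60.0  # um
        k_of_lam = wavelength_to_k(self.lam)
        fringe = np.cos(2 * k_of_lam * z)
        k, res = resample_to_k(fringe, self.lam)
        spec = np.abs(np.fft.fft(res))[: len(k) // 2]
        pitch = math.pi / (len(k) * (k[1] - k[0]))
        assert int(np.argmax(spec)) == int(round(z / pitch))

    def test_rejects_nonmonotone_calibration(self):
        bad = self.lam.copy()
        bad[100] = bad[99]
        with pytest.raises(ValueError, match="monotone"):
            resample_to_k(np.ones(512), bad)


class TestRemoveBackground:
    def test_identical_lines_estimate_gives_zero(self):
        counts = np.tile(np.arange(64, dtype=np.uint16), (3, 3, 1))
        vol = v.SpectralVolume(counts, np.linspace(425, 685, 64))
        out = v.remove_background(vol, "estimate")
        np.testing.assert_array_equal(out, 0.0)

    def test_zero_background_is_identity(self):
        counts = np.random.default_rng(0).integers(0, 4096, (2, 2, 64)).astype(np.uint16)
        vol = v.SpectralVolume(counts, np.linspace(425, 685, 64))
        out = v.remove_background(vol, np.zeros(64))
        np.testing.assert_array_equal(out, counts.astype(float))

    def test_length_mismatch_rejected(self):
        counts = np.zeros((2, 2, 64), dtype=np.uint16)
        vol = v.SpectralVolume(counts, np.linspace(425, 685, 64))
        with pytest.raises(ValueError, match="length"):
            v.remove_background(vol, np.zeros(32))

    def test_dc_suppressed_on_random_phase_batch(self):
        """Mean-spectrum subtraction removes the DC pedestal by >= 20 dB
        relative to the fringe peak on a batch with random fringe phase."""
        rng = np.random.default_rng(7)
        lam = np.linspace(425.0, 685.0, 512)
        k = wavelength_to_k(lam)
        n_lines = 64
        counts = np.empty((n_lines, 1, 512))
        for i in range(n_lines):
            phase = rng.uniform(0, 2 * math.pi)
            counts[i, 0] = 1000.0 + 100.0 * np.cos(2 * k * 50.0 + phase)
        vol = v.SpectralVolume(counts.astype(np.uint16), lam)
        tom_raw = v.reconstruct(vol, background=np.zeros(512))
        tom_est = v.reconstruct(vol, background="estimate")
        dc_raw = tom_raw.intensity[..., 0].mean()
        dc_est = tom_est.intensity[..., 0].mean()
        fringe_peak = tom_est.intensity[..., 5:].max()
        assert 10 * math.log10(dc_raw / max(dc_est, 1e-30)) >= 20
        assert fringe_peak > 100 * dc_est


class TestApplyDispersion:
    k = np.linspace(9.0, 15.0, 256)

    def test_zero_model_is_identity(self):
        spec = np.random.default_rng(1).normal(size=256) + 0j
        model = v.DispersionModel(k0=12.0, coeffs=())
        np.testing.assert_array_equal(v.apply_dispersion(spec, self.k, model), spec)

    def test_model_and_negation_invert(self):
        spec = np.random.default_rng(2).normal(size=256) + 0j
        model = v.DispersionModel(k0=12.0, coeffs=(4.0, -1.5))
        out = v.apply_dispersion(
            v.apply_dispersion(spec, self.k, model), self.k, model.negated()
        )
        np.testing.assert_allclose(out, spec, rtol=1e-12, atol=1e-12)

    def test_magnitude_preserved(self):
        spec = np.random.default_rng(3).normal(size=256) + 0j
        model = v.DispersionModel(k0=12.0, coeffs=(7.0, 2.0, 0.5))
        out = v.apply_dispersion(spec, self.k, model)
        np.testing.assert_allclose(np.abs(out), np.abs(spec), rtol=1e-12)

    def test_order_limit(self):
        with pytest.raises(ValueError):
            v.DispersionModel(k0=12.0, coeffs=(1.0, 1.0, 1.0, 1.0, 1.0))


class TestReconstruct:
    def test_single_reflector_peak_depth(self, quiet_instrument, reference_spectrum):
        z = 95.0
        truth = v.point_target_truth(z_um=z)
        vol = v.simulate_volume(truth, quiet_instrument, seed=1)
        tom = v.reconstruct(vol, background=reference_spectrum)
        inten = tom.intensity[0, 0].copy()
        inten[:5] = 0
        expected = (quiet_instrument.z_offset_um + z) / tom.axial_pitch_um
        assert abs(int(np.argmax(inten)) - expected) <= 1.0

    def test_parseval(self, quiet_instrument, reference_spectrum):
        truth = v.point_target_truth(z_um=60.0)
        vol = v.simulate_volume(truth, quiet_instrument, seed=2)
        tom = v.reconstruct(vol, background=reference_spectrum, keep="full")
        n = vol.dims[-1]
        from visocm.reconstruct import _corrected_k_spectra

        _, spectra, _ = _corrected_k_spectra(vol, background=reference_spectrum)
        lhs = np.abs(tom.field) ** 2
        assert lhs.sum() == pytest.approx(n * (np.abs(spectra) ** 2).sum(), rel=1e-6)

    def test_two_reflectors_resolved_at_2um(self, quiet_instrument, reference_spectrum):
        """Two scatterers 2 um apart (optical) resolve with the full band
        (theoretical Gaussian resolution ~0.87 um)."""
        truth = v.point_target_truth(z_um=80.0)
        t2 = v.point_target_truth(z_um=82.0)
        truth.scat_z_um = np.concatenate([truth.scat_z_um, t2.scat_z_um])
        truth.scat_x = np.concatenate([truth.scat_x, t2.scat_x])
        truth.scat_y = np.concatenate([truth.scat_y, t2.scat_y])
        truth.scat_amp = np.concatenate([truth.scat_amp, t2.scat_amp])
        truth.scat_profile_id = np.concatenate([truth.scat_profile_id, t2.scat_profile_id])
        truth.scat_abs_od = np.zeros((2, 0))
        vol = v.simulate_volume(truth, quiet_instrument, seed=3)
        tom = v.reconstruct(vol, background=reference_spectrum, pad_factor=8)
        inten = tom.intensity[0, 0].copy()
        inten[: 40 * 8] = 0
        pk = int(np.argmax(inten))
        # local minimum between two local maxima ~2 um apart
        window = inten[pk - 40 : pk + 40]
        peaks = [
            i
            for i in range(1, len(window) - 1)
            if window[i] > window[i - 1] and window[i] > window[i + 1]
            and window[i] > 0.2 * window.max()
        ]
        assert len(peaks) >= 2
        sep_um = (max(peaks) - min(peaks)) * tom.axial_pitch_um
        assert sep_um == pytest.approx(2.0, abs=0.7)


class TestEstimateDispersion:
    def _mirror_volume(self, inst, injected, seed=3):
        truth = v.point_target_truth(z_um=60.0, lateral_shape=(4, 4), z_step_per_line_um=3.0)
        return v.simulate_volume(truth, inst, dispersion=injected, seed=seed)

    def test_null_case_recovers_near_zero(self, quiet_instrument, reference_spectrum):
        vol = self._mirror_volume(quiet_instrument, None)
        est = v.estimate_dispersion(vol, order=3, background=reference_spectrum)
        # tolerance: coefficients small enough that PSF broadening is < 1%
        tom0 = v.reconstruct(vol, background=reference_spectrum, pad_factor=8)
        tom1 = v.reconstruct(vol, est, background=reference_spectrum, pad_factor=8)
        f0 = peak_fwhm(tom0.intensity[0, 0], tom0.axial_pitch_um)
        f1 = peak_fwhm(tom1.intensity[0, 0], tom1.axial_pitch_um)
        assert f1 <= 1.01 * f0

    def test_injected_mismatch_corrected(self, quiet_instrument, reference_spectrum):
        k0 = float(np.mean(wavelength_to_k(quiet_instrument.wavelengths_nm)))
        injected = v.DispersionModel(k0=k0, coeffs=(6.0, 1.0))
        vol = self._mirror_volume(quiet_instrument, injected)
        est = v.estimate_dispersion(vol, order=3, background=reference_spectrum)
        tom_corr = v.reconstruct(vol, est, background=reference_spectrum, pad_factor=8)
        vol0 = self._mirror_volume(quiet_instrument, None)
        tom_ideal = v.reconstruct(vol0, background=reference_spectrum, pad_factor=8)
        f_corr = np.mean(
            [peak_fwhm(tom_corr.intensity[i, j], tom_corr.axial_pitch_um) for i in range(4) for j in range(4)]
        )
        f_ideal = np.mean(
            [peak_fwhm(tom_ideal.intensity[i, j], tom_ideal.axial_pitch_um) for i in range(4) for j in range(4)]
        )
        assert f_corr <= 1.1 * f_ideal

    def test_invariant_to_depth_shift(self, quiet_instrument, reference_spectrum):
        """A global depth shift (linear phase) does not change the
        estimated quadratic/cubic coefficients."""
        vol_a = self._mirror_volume(quiet_instrument, None, seed=3)
        truth_b = v.point_target_truth(z_um=75.0, lateral_shape=(4, 4), z_step_per_line_um=3.0)
        vol_b = v.simulate_volume(truth_b, quiet_instrument, seed=3)
        est_a = v.estimate_dispersion(vol_a, order=2, background=reference_spectrum)
        est_b = v.estimate_dispersion(vol_b, order=2, background=reference_spectrum)
        assert abs(est_a.coeffs[0] - est_b.coeffs[0]) < 0.5


class TestDetectSurface:
    def _tomo(self, inten):
        return Tomogram(field=np.sqrt(inten).astype(complex), axial_pitch_um=1.0)

    def test_noiseless_step_found_exactly(self):
        inten = np.zeros((4, 4, 200))
        inten[..., 40:120] = 100.0
        surf = v.detect_surface(self._tomo(inten), min_fraction_of_max=0.05)
        assert np.all(surf.valid_mask)
        assert np.all(surf.surface_index == 40)

    def test_pure_noise_all_invalid(self):
        rng = np.random.default_rng(0)
        inten = rng.exponential(1.0, (6, 6, 300))
        surf = v.detect_surface(self._tomo(inten))
        assert not surf.valid_mask.any()

    def test_tilted_surface_slope_recovered(self):
        inst = v.InstrumentSpec(n_spectral_pixels=1024, noise=v.NoiseModel(0, 0, 0))
        truth = phantoms.homogeneous_tissue(
            0.35,
            lateral_shape=(16, 8),
            tilt=(0.8, 0.0),
            regular=True,
            density_um=2.5,
            extent_um=100.0,
        )
        vol = v.simulate_volume(truth, inst, seed=4)
        tom = v.reconstruct(vol)
        surf = v.detect_surface(tom)
        assert surf.valid_mask.mean() > 0.9
        # least-squares plane fit along x, compare with true tilt
        xs = np.arange(16)
        mean_idx = np.array(
            [surf.surface_index[i][surf.valid_mask[i]].mean() for i in range(16)]
        )
        slope_px = np.polyfit(xs, mean_idx, 1)[0]
        # surface tilt of 0.8 um/um lateral, pitch 1 um laterally
        expected = 0.8 / tom.axial_pitch_um
        assert slope_px == pytest.approx(expected, abs=1.0 / tom.axial_pitch_um * 0.25)


class TestEnfaceProjection:
    def test_constant_volume(self):
        inten = np.full((3, 3, 50), 4.2)
        tom = Tomogram(field=np.sqrt(inten).astype(complex), axial_pitch_um=2.0)
        surf = SurfaceMap(np.full((3, 3), 5), np.ones((3, 3), bool))
        img = v.enface_projection(tom, surf, 0.0, 40.0)
        np.testing.assert_allclose(img, 4.2, rtol=1e-6)

    def test_three_voxel_mean(self):
        inten = np.zeros((1, 1, 10))
        inten[0, 0, 3:6] = [1.0, 2.0, 3.0]
        tom = Tomogram(field=np.sqrt(inten).astype(complex), axial_pitch_um=1.0)
        surf = SurfaceMap(np.array([[3]]), np.ones((1, 1), bool))
        img = v.enface_projection(tom, surf, 0.0, 3.0)
        assert img[0, 0] == pytest.approx(2.0)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(5)
        inten = rng.random((6, 5, 64))
        tom = Tomogram(field=np.sqrt(inten).astype(complex), axial_pitch_um=1.7)
        surf = SurfaceMap(
            rng.integers(3, 10, (6, 5)), rng.random((6, 5)) > 0.2
        )
        d0, d1 = 4.0, 30.0
        img = v.enface_projection(tom, surf, d0, d1)
        for ix in range(6):
            for iy in range(5):
                if not surf.valid_mask[ix, iy]:
                    assert np.isnan(img[ix, iy])
                    continue
                lo = surf.surface_index[ix, iy] + math.floor(d0 / 1.7)
                hi = surf.surface_index[ix, iy] + math.ceil(d1 / 1.7)
                assert img[ix, iy] == pytest.approx(inten[ix, iy, lo:hi].mean())

    def test_offset_invariance(self):
        rng = np.random.default_rng(6)
        inten = rng.random((4, 4, 80))
        surf_idx = rng.integers(5, 15, (4, 4))
        valid = np.ones((4, 4), bool)
        tom = Tomogram(field=np.sqrt(inten).astype(complex), axial_pitch_um=1.0)
        img = v.enface_projection(tom, SurfaceMap(surf_idx, valid), 0.0, 20.0)
        shifted = np.roll(inten, 7, axis=-1)
        tom2 = Tomogram(field=np.sqrt(shifted).astype(complex), axial_pitch_um=1.0)
        img2 = v.enface_projection(tom2, SurfaceMap(surf_idx + 7, valid), 0.0, 20.0)
        np.testing.assert_allclose(img, img2, rtol=1e-12)

    def test_depth_linearity_of_reflectors(self, quiet_instrument, reference_spectrum):
        bins = {}
        for z in (50.0, 100.0):
            truth = v.point_target_truth(z_um=z)
            vol = v.simulate_volume(truth, quiet_instrument, seed=7)
            tom = v.reconstruct(vol, background=reference_spectrum)
            inten = tom.intensity[0, 0].copy()
            inten[:5] = 0
            bins[z] = int(np.argmax(inten))
        off = quiet_instrument.z_offset_um / tom.axial_pitch_um
        assert (bins[100.0] - off) / (bins[50.0] - off) == pytest.approx(2.0, abs=0.05)
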