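"""Global (exponential-fit) and local (per-pixel) attenuation estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import visocm as v
from visocm.atten import local_attenuation, fit_global_attenuation, attenuation_enface
from visocm.reconstruct import SurfaceMap


class TestLocalAttenuation:
    def test_two_pixel_example(self):
        mu = local_attenuation(np.array([3.0, 1.0]), delta_mm=0.5)
        assert mu[0] == pytest.approx(math.log(4.0), rel=1e-12)  # ln(1+3/1)/(2*0.5)

    def test_equal_pair(self):
        mu = local_attenuation(np.array([5.0, 5.0]), delta_mm=1.0)
        assert mu[0] == pytest.approx(math.log(2.0) / 2.0, rel=1e-12)

    def test_geometric_series_closed_form(self):
        """On round-trip exponential decay the estimator is exact for
        interior pixels: 1 + I[i]/tail = e^{2 mu delta}."""
        mu_true, delta = 0.8, 0.004
        n = 4000
        I = np.exp(-2 * mu_true * delta * np.arange(n))
        mu = local_attenuation(I, delta)
        interior = mu[: n // 2]
        np.testing.assert_allclose(interior, mu_true, rtol=1e-3)

    def test_truncation_biases_only_the_tail(self):
        mu_true, delta = 0.8, 0.004
        n = 4000
        I = np.exp(-2 * mu_true * delta * np.arange(n))
        mu = local_attenuation(I, delta)
        # bias at half depth still < 0.1%, last pixels inflated
        assert abs(mu[n // 2] / mu_true - 1) < 1e-3
        assert mu[-2] > 2 * mu_true

    def test_last_pixel_invalid_and_zero_tail_sentinel(self):
        mu = local_attenuation(np.array([1.0, 2.0, 0.0]), delta_mm=1.0)
        assert np.isnan(mu[-1])
        assert np.isinf(mu[1])  # nonzero pixel, zero tail

    def test_matches_brute_force_tail_sums(self):
        rng = np.random.default_rng(1)
        I = rng.random(50)
        mu = local_attenuation(I, 0.01)
        for i in range(49):
            tail = I[i + 1 :].sum()
            expected = math.log1p(I[i] / tail) / 0.02 if tail > 0 else math.inf
            assert mu[i] == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        I = np.exp(-0.1 * np.arange(100))
        base = local_attenuation(I, 0.01)
        scaled = local_attenuation(I * scale, 0.01)
        np.testing.assert_allclose(scaled[:-1], base[:-1], rtol=1e-9)


class TestGlobalFit:
    def test_exact_recovery_noiseless(self):
        z = np.arange(300) * 1e-3  # mm
        I = 7.0 * np.exp(-0.39 * z)
        fit = fit_global_attenuation(I, 0, 0.2, 1e-3)
        assert fit.valid
        assert fit.mu_t == pytest.approx(0.39, rel=1e-6)
        assert fit.i0 == pytest.approx(7.0, rel=1e-6)

    def test_constant_ascan_gives_zero(self):
        fit = fit_global_attenuation(np.full(100, 3.0), 0, 0.05, 1e-3)
        assert fit.valid
        assert fit.mu_t == pytest.approx(0.0, abs=1e-9)

    def test_short_window_invalid_not_raising(self):
        fit = fit_global_attenuation(np.ones(10), 8, 0.2, 1e-3)
        assert not fit.valid

    @pytest.mark.parametrize("mu_true", [0.35, 0.39])
    def test_noisy_recovery_within_5_percent(self, mu_true):
        """Mean recovered mu over 200 noisy A-scans stays within 5%."""
        rng = np.random.default_rng(42)
        z = np.arange(250) * 1e-3
        recovered = []
        for _ in range(200):
            I = np.exp(-mu_true * z) * (1 + 0.05 * rng.standard_normal(z.size))
            fit = fit_global_attenuation(np.clip(I, 1e-9, None), 0, 0.2, 1e-3)
            recovered.append(fit.mu_t)
        assert np.mean(recovered) == pytest.approx(mu_true, rel=0.05)

    def test_log_regression_oracle_agreement(self):
        """Weighted log-domain regression (independent oracle) agrees with
        the nonlinear fit on clean data."""
        z = np.arange(200) * 1e-3
        I = 3.0 * np.exp(-0.5 * z)
        fit = fit_global_attenuation(I, 0, 0.15, 1e-3)
        n = int(round(0.15 / 1e-3))
        slope = np.polyfit(z[:n], np.log(I[:n]), 1)[0]
        assert fit.mu_t == pytest.approx(-slope, rel=1e-6)

    def test_roundtrip_flag_halves_rate(self):
        z = np.arange(300) * 1e-3
        I = np.exp(-2 * 0.39 * z)
        single = fit_global_attenuation(I, 0, 0.2, 1e-3, roundtrip="single")
        double = fit_global_attenuation(I, 0, 0.2, 1e-3, roundtrip="double")
        assert single.mu_t == pytest.approx(2 * 0.39, rel=1e-6)
        assert double.mu_t == pytest.approx(0.39, rel=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-2, max_value=1e2))
    def test_scale_invariance_of_mu(self, scale):
        z = np.arange(200) * 1e-3
        I = np.exp(-0.4 * z)
        a = fit_global_attenuation(I, 0, 0.15, 1e-3)
        b = fit_global_attenuation(I * scale, 0, 0.15, 1e-3)
        assert b.mu_t == pytest.approx(a.mu_t, rel=1e-9)
        assert b.i0 == pytest.approx(a.i0 * scale, rel=1e-6)

    def test_pitch_invariance(self):
        """Halving the pixel size with the same physical profile leaves
        mu (per mm) unchanged."""
        z1 = np.arange(200) * 1e-3
        z2 = np.arange(400) * 5e-4
        a = fit_global_attenuation(np.exp(-0.5 * z1), 0, 0.15, 1e-3)
        b = fit_global_attenuation(np.exp(-0.5 * z2), 0, 0.15, 5e-4)
        assert a.mu_t == pytest.approx(b.mu_t, rel=1e-6)

    def test_global_matches_local_on_single_exponential(self):
        """After reconciling the round-trip conventions the two estimators
        agree on noiseless exponential volumes within 1%."""
        mu_true, delta = 0.6, 0.002
        n = 4000
        I = np.exp(-2 * mu_true * delta * np.arange(n))
        glob = fit_global_attenuation(I, 0, 1.0, delta, roundtrip="double")
        loc = local_attenuation(I, delta)
        assert glob.mu_t == pytest.approx(mu_true, rel=1e-6)
        assert np.nanmean(loc[: n // 2]) == pytest.approx(glob.mu_t, rel=0.01)


class TestAttenuationEnface:
    def test_constant_slab(self):
        mu = np.full((3, 3, 60), 0.7)
        surf = SurfaceMap(np.full((3, 3), 5), np.ones((3, 3), bool))
        out = attenuation_enface(mu, surf, 0.0, 40.0, axial_pitch_um=1.0)
        np.testing.assert_allclose(out, 0.7)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        mu = rng.random((5, 4, 70))
        mu[1, 1, 10] = np.inf  # sentinel excluded
        surf = SurfaceMap(rng.integers(2, 8, (5, 4)), np.ones((5, 4), bool))
        out = attenuation_enface(mu, surf, 2.0, 30.0, axial_pitch_um=1.3)
        for ix in range(5):
            for iy in range(4):
                lo = surf.surface_index[ix, iy] + math.floor(2.0 / 1.3)
                hi = surf.surface_index[ix, iy] + math.ceil(30.0 / 1.3)
                vals = mu[ix, iy, lo:hi]
                vals = vals[np.isfinite(vals)]
                assert out[ix, iy] == pytest.approx(vals.mean())

    def test_two_region_truth_recovery(self):
        """A synthetic two-region volume (0.39 vs 0.35/mm round-trip
        decay, long tails, mild noise) maps back to its ground truth
        within 10% with the correct ordering."""
        rng = np.random.default_rng(11)
        delta = 0.004  # mm
        nz = 3000
        z = np.arange(nz) * delta
        vol = np.empty((8, 8, nz))
        for ix in range(8):
            mu_true = 0.39 if ix < 4 else 0.35
            base = np.exp(-2 * mu_true * z)
            vol[ix] = base * (1 + 0.03 * rng.standard_normal((8, nz)))
        vol = np.clip(vol, 1e-12, None)
        mu_loc = local_attenuation(vol, delta)
        surf = SurfaceMap(np.zeros((8, 8), int), np.ones((8, 8), bool))
        # slab in um: pitch is 4 um here
        en = attenuation_enface(mu_loc, surf, 0.0, 400.0, axial_pitch_um=delta * 1e3)
        wm, gm = en[:4].mean(), en[4:].mean()
        assert wm == pytest.approx(0.39, rel=0.10)
        assert gm == pytest.approx(0.35, rel=0.10)
        assert wm > gm

    def test_no_valid_pixels_gives_nan(self):
        mu = np.full((2, 2, 30), np.nan)
        surf = SurfaceMap(np.zeros((2, 2), int), np.ones((2, 2), bool))
        out = attenuation_enface(mu, surf, 0.0, 20.0, axial_pitch_um=1.0)
        assert np.isnan(out).all()


class TestEndToEndContrast:
    def test_wm_brighter_and_mu_plausible(self, quiet_instrument):
        """Full simulated two-region cortex: the white-matter half is
        brighter, and region-mean global fits land in the plausible
        tissue range around the ground truth."""
        from visocm import phantoms
        from visocm.atten import mean_aligned_ascan

        inst = v.InstrumentSpec(
            n_spectral_pixels=2048, noise=v.NoiseModel(0, 0, 0), reference_level=15.0
        )
        truth = phantoms.cortex_two_region(nx_half=10, ny=12, regular=True)
        vol = v.simulate_volume(truth, inst, seed=1)
        tom = v.reconstruct(vol)
        delta_opt = tom.axial_pitch_um * 1e-3
        inten = tom.intensity * 10 ** (24 * np.arange(tom.n_depth) * delta_opt / 10)
        surf = v.detect_surface(tom)
        wm_i = inten[:10][..., 80:180].mean()
        gm_i = inten[10:][..., 80:180].mean()
        assert wm_i > 1.5 * gm_i
        delta_geo = delta_opt / truth.refractive_index
        mus = []
        for sl in (slice(0, 10), slice(10, 20)):
            sub = SurfaceMap(surf.surface_index[sl], surf.valid_mask[sl])
            prof, _ = mean_aligned_ascan(inten[sl], sub, n_keep=210)
            fit = v.fit_global_attenuation(prof, 8, 0.10, delta_geo, roundtrip="double")
            mus.append(fit.mu_t)
        for m in mus:
            assert 0.2 < m < 0.6
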