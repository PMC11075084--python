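"""Inference: decay fits, Stern-Volmer, spectral decomposition, global fits, yields."""

import numpy as np
import pytest
from dataclasses import replace

from conftest import bare_rates
from indokin import synth
from indokin.inference import (decompose_spectrum, exp_conv_gauss, fit_decay,
                               global_target_fit, quantum_yields, stern_volmer)
from indokin.kinetics import (KineticScheme, build_scheme, drain_eigenvalues,
                              propagate, scheme_from_dict)
from indokin.spectra import build_default_library


class TestExpConvGauss:
    def test_reduces_to_step_exponential_without_irf(self):
        t = np.linspace(-1.0, 5.0, 100)
        out = exp_conv_gauss(t, 1.0, 0.0)
        ref = np.where(t >= 0, np.exp(-np.clip(t, 0, None)), 0.0)
        assert np.allclose(out, ref)

    def test_half_height_at_time_zero_for_slow_decay(self):
        # tau >> sigma: the convolution is ~0.5 at t = 0
        assert exp_conv_gauss(np.array([0.0]), 1e3, 1.0)[0] == pytest.approx(0.5, rel=1e-3)

    def test_numerically_stable_for_extreme_ratio(self):
        out = exp_conv_gauss(np.linspace(0, 1e-9, 11), 1e-12, 1e-10)
        assert np.all(np.isfinite(out)) and np.all(out >= 0)


class TestFitDecay:
    def test_noiseless_single_exponential_self_consistency(self):
        t = np.linspace(0, 30e-9, 400)
        y = 100.0 * np.exp(-t / 4.56e-9)
        fit = fit_decay(t, y, 1, 0.0, "uniform")
        assert fit.converged
        assert fit.value("tau1") == pytest.approx(4.56e-9, rel=1e-6)

    def test_noiseless_biexponential_recovery(self):
        """Equal-amplitude tau = {1, 10} recovered to 1e-4, sorted ascending."""
        t = np.linspace(0.0, 50.0, 800)
        y = np.exp(-t / 1.0) + np.exp(-t / 10.0)
        fit = fit_decay(t, y, 2, 0.0, "uniform")
        assert fit.value("tau1") == pytest.approx(1.0, rel=1e-4)
        assert fit.value("tau2") == pytest.approx(10.0, rel=1e-4)
        assert fit.value("tau1") < fit.value("tau2")

    def test_poisson_histogram_within_1pct(self):
        """1e6-count Poisson histogram of a 4.56 ns decay recovered within 1%."""
        from indokin.forward import ExperimentGeometry, simulate_tcspc

        geo = ExperimentGeometry(path_length=1.0, c_exc=1e-6, irf_fwhm=1e-10,
                                 time_zero=2e-9, regime="nano")
        sch = build_scheme("water", 268)
        h = simulate_tcspc(sch, geo, 4096, 12.2e-12, 1_000_000, seed=13,
                           decay=lambda t: np.exp(-t / 4.56e-9))
        fit = fit_decay(h.times, h.counts, 1, 1e-10, "poisson", t0=2e-9)
        assert fit.value("tau1") == pytest.approx(4.56e-9, rel=0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_decay(np.arange(10.0), np.ones(10), 1, 0.0)


class TestSternVolmer:
    def test_exact_line_recovers_nitrate_constant(self):
        """1/tau = 1/4.56 ns + 7.6e9 c reproduced exactly, r^2 = 1."""
        c = np.array([0.0, 0.1, 0.25, 0.5])
        tau = 1.0 / (1.0 / 4.56e-9 + 7.6e9 * c)
        res = stern_volmer(tau, c)
        assert res.k_q == pytest.approx(7.6e9, rel=1e-10)
        assert res.tau0 == pytest.approx(4.56e-9, rel=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_response_gives_zero_slope(self):
        res = stern_volmer([4.56e-9] * 4, [0.0, 0.1, 0.2, 0.5])
        assert abs(res.k_q) < 1e-3

    def test_noisy_recovery_within_5pct(self):
        """k = 4.45e9 with 1% lifetime noise on 5 points recovered within 5%."""
        rng = np.random.default_rng(21)
        c = np.array([0.0, 0.1, 0.2, 0.35, 0.5])
        tau = 1.0 / (1.0 / 4.56e-9 + 4.45e9 * c)
        tau_noisy = tau * (1.0 + 0.01 * rng.standard_normal(len(c)))
        res = stern_volmer(tau_noisy, c)
        assert res.k_q == pytest.approx(4.45e9, rel=0.05)

    def test_unbiased_over_replicates(self):
        """Mean recovered slope over 200 seeded replicates is unbiased at 1% noise."""
        c = np.array([0.0, 0.1, 0.25, 0.5])
        tau = 1.0 / (1.0 / 4.56e-9 + 7.6e9 * c)
        ks = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            ks.append(stern_volmer(tau * (1 + 0.01 * rng.standard_normal(4)), c).k_q)
        mean = np.mean(ks)
        sem = np.std(ks) / np.sqrt(len(ks))
        assert abs(mean - 7.6e9) < 3 * sem + 0.002 * 7.6e9

    def test_input_validation(self):
        with pytest.raises(ValueError):
            stern_volmer([1e-9, 2e-9], [0.0, 0.1])
        with pytest.raises(ValueError):
            stern_volmer([1e-9, -1e-9, 2e-9], [0.0, 0.1, 0.2])
        with pytest.raises(ValueError):  # no zero, narrow span
            stern_volmer([1e-9, 1e-9, 1e-9], [0.1, 0.12, 0.15])


class TestDecomposeSpectrum:
    def test_exact_linear_recovery(self, water_library):
        """A 0.3 cation + 0.7 electron mixture decomposes exactly."""
        lam = np.linspace(320.0, 750.0, 200)
        basis = [water_library["cation"], water_library["e_separated"]]
        scale = 1000.0 * 0.02 * 1.2e-4
        y = scale * (0.3 * basis[0].epsilon(lam, np.inf)
                     + 0.7 * basis[1].epsilon(lam, np.inf))
        coef, resid, rms = decompose_spectrum(lam, y, basis, 0.02, 1.2e-4)
        assert coef["cation"] == pytest.approx(0.3, abs=1e-8)
        assert coef["e_separated"] == pytest.approx(0.7, abs=1e-8)
        assert rms < 1e-10

    def test_nnls_boundary_zero_coefficient(self, water_library):
        """A slice with negative projection on a basis member pins it to zero."""
        lam = np.linspace(320.0, 750.0, 200)
        basis = [water_library["cation"], water_library["e_separated"]]
        y = (water_library["e_separated"].epsilon(lam, np.inf)
             - 0.3 * water_library["cation"].epsilon(lam, np.inf))
        coef, _, _ = decompose_spectrum(lam, y, basis, 1.0, 1e-3)
        assert coef["cation"] == 0.0

    def test_invariance_under_geometry_rescale(self, water_library):
        lam = np.linspace(320.0, 750.0, 150)
        basis = [water_library["e_separated"]]
        y = 1000.0 * 0.1 * 1e-5 * 0.5 * basis[0].epsilon(lam, np.inf)
        c1, _, _ = decompose_spectrum(lam, y, basis, 0.1, 1e-5)
        c2, _, _ = decompose_spectrum(lam, y, basis, 0.5, 2e-6)  # same product
        assert c1["e_separated"] == pytest.approx(c2["e_separated"], rel=1e-10)

    def test_200nm_reconstruction_missing_400_550(self, water_library,
                                                  coarse_wavelengths, coarse_times):
        """Cation + electron alone cannot explain 400-550 nm at 500 ps (200 nm pump)."""
        ds = synth.generate_ta_dataset("water", 200, noise_sigma=0.0,
                                       wavelengths=coarse_wavelengths,
                                       times=coarse_times)
        i500 = np.argmin(np.abs(ds.ta.times - 500e-12))
        basis = [water_library["cation"], water_library["e_separated"]]
        _, resid, _ = decompose_spectrum(ds.ta.wavelengths, ds.ta.dod[i500],
                                         basis, 0.02, 1.2e-4)
        wl = ds.ta.wavelengths
        mid = (wl >= 400) & (wl <= 550)
        out = ~mid
        assert np.nanmean(resid[mid]) > 3 * abs(np.nanmean(resid[out]))

    def test_error_paths(self, water_library):
        lam = np.linspace(320.0, 750.0, 10)
        with pytest.raises(ValueError):
            decompose_spectrum(lam, np.full(10, np.nan),
                               [water_library["cation"]], 0.1, 1e-5)
        with pytest.raises(ValueError):
            decompose_spectrum(lam, np.ones(10), [], 0.1, 1e-5)


class TestGlobalTargetFit:
    def test_zero_noise_self_consistency(self, water_library, coarse_wavelengths,
                                         coarse_times):
        """k_diss recovered to 1e-3 relative from its own zero-noise dataset."""
        ds = synth.generate_ta_dataset("water", 268, noise_sigma=0.0,
                                       wavelengths=coarse_wavelengths,
                                       times=coarse_times)
        truth = scheme_from_dict(ds.truth["scheme"])
        tmpl = replace(truth, rates=replace(truth.rates, k_diss=truth.rates.k_diss * 2.5))
        fit, _ = global_target_fit(ds.ta, tmpl, ["k_diss"], water_library,
                                   spectra_mode="library")
        assert fit.converged
        assert fit.value("k_diss") == pytest.approx(truth.rates.k_diss, rel=1e-3)

    def test_spectral_recovery_on_distinct_profiles(self, water_library,
                                                    coarse_wavelengths, coarse_times):
        """Free-spectra fit recovers the electron spectrum (cos > 0.98) when the
        electron kinetics are distinct from its geminate cation (H+ present)."""
        ds = synth.generate_ta_dataset(
            "water", 200, scavenger={"species": "H+", "concentration": 0.2},
            noise_sigma=0.0, wavelengths=coarse_wavelengths, times=coarse_times)
        truth = scheme_from_dict(ds.truth["scheme"])
        tmpl = replace(truth, rates=replace(truth.rates, k_gem=truth.rates.k_gem * 2))
        fit, sas = global_target_fit(ds.ta, tmpl, ["k_gem"], water_library,
                                     spectra_mode="free")
        assert fit.value("k_gem") == pytest.approx(truth.rates.k_gem, rel=0.02)
        rec = sas["e_separated"]
        ref = water_library["e_separated"].epsilon(ds.ta.wavelengths, np.inf)
        cos = rec @ ref / (np.linalg.norm(rec) * np.linalg.norm(ref))
        assert cos > 0.98

    def test_noisy_recovery_within_10pct(self, water_library, coarse_wavelengths,
                                         coarse_times):
        ds = synth.generate_ta_dataset("water", 268, noise_sigma=0.15, seed=5,
                                       wavelengths=coarse_wavelengths,
                                       times=coarse_times)
        truth = scheme_from_dict(ds.truth["scheme"])
        tmpl = replace(truth, rates=replace(truth.rates, k_diss=truth.rates.k_diss * 2.5))
        fit, _ = global_target_fit(ds.ta, tmpl, ["k_diss"], water_library,
                                   spectra_mode="library")
        assert fit.value("k_diss") == pytest.approx(truth.rates.k_diss, rel=0.10)
        assert fit.residual_rms <= 0.15 * 1.05

    def test_unidentifiable_parameter_flagged(self, water_library,
                                              coarse_wavelengths, coarse_times):
        """k_gem has no effect at 268 nm: the fit returns, covariance withheld."""
        ds = synth.generate_ta_dataset("water", 268, noise_sigma=0.0,
                                       wavelengths=coarse_wavelengths,
                                       times=coarse_times)
        truth = scheme_from_dict(ds.truth["scheme"])
        fit, _ = global_target_fit(ds.ta, truth, ["k_diss", "k_gem"], water_library,
                                   spectra_mode="library")
        assert fit.covariance_available is False


class TestQuantumYields:
    def test_radiative_branching_identity(self):
        """k_rad = k_ic with no other channels gives phi_fluorescence = 1/2."""
        rates = bare_rates(k_rad=1e8, k_ic=1e8)
        sch = KineticScheme(rates=rates, solvent="water", excitation_nm=268,
                            scavenger=None, initial_conditions={"La": 1.0},
                            c_exc=1e-5)
        conc = propagate(sch, np.geomspace(1e-12, 2e-7, 3000))
        phi = quantum_yields(conc, rates, 2e-7)
        assert phi["phi_fluorescence"] == pytest.approx(0.5, abs=2e-4)
        assert phi["phi_ground_recovery"] == pytest.approx(0.5, abs=2e-4)

    def test_drain_branching_from_eigenrates(self):
        """No recombination: phi_e equals the closed-form drain branching ratio."""
        kf, kb, kd, kr, kic = 2.5e10, 1e11, 8e8, 5e7, 3e7
        rates = bare_rates(k_rad=kr, k_ic=kic, k_pair_f=kf, k_pair_b=kb, k_diss=kd)
        sch = KineticScheme(rates=rates, solvent="water", excitation_nm=268,
                            scavenger=None, initial_conditions={"La": 1.0},
                            c_exc=1e-12)   # recombination negligible
        conc = propagate(sch, np.geomspace(1e-13, 1e-6, 4000))
        phi = quantum_yields(conc, rates, 1e-6)
        a, b = kr + kic + kf, kb + kd
        phi_expected = kd * kf / (a * b - kf * kb)
        assert phi["phi_electron_separated"] == pytest.approx(phi_expected, rel=1e-4)

    def test_yields_sum_to_one_for_closed_scheme(self, water_scheme_268):
        conc = propagate(water_scheme_268, np.geomspace(1e-14, 1e-6, 6000))
        phi = quantum_yields(conc, water_scheme_268.rates, 1e-6)
        total = sum(phi.values())
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_horizon_validation(self, water_scheme_268):
        conc = propagate(water_scheme_268, np.geomspace(1e-14, 1e-7, 100))
        with pytest.raises(ValueError):
            quantum_yields(conc, water_scheme_268.rates, 1e-6)
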