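"""Generator correctness: spectra, scenarios, kinetics and determinism."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cbxscreen.config import AssayConfig
from cbxscreen.errors import ContractError
from cbxscreen.simulate import (
    GaussianBand,
    GroundTruth,
    default_wavelengths,
    gaussian_spectrum,
    isosbestic_band_pair,
    simulate_kinetics_series,
    simulate_stability_scenario,
)


class TestGaussianSpectrum:
    def test_peak_value_linearity_and_width_point(self):
        wl = np.array([330.0, 350.0, 370.0])
        band = GaussianBand(350.0, 20.0, 1.0)
        one = gaussian_spectrum([band], wl)
        assert one[1] == pytest.approx(1.0)
        # center +- width -> height * exp(-1/2)
        assert one[0] == pytest.approx(math.exp(-0.5))
        assert one[2] == pytest.approx(math.exp(-0.5))
        two = gaussian_spectrum([band, band], wl)
        np.testing.assert_allclose(two, 2 * one)

    def test_empty_band_list_is_zero_spectrum(self):
        np.testing.assert_array_equal(
            gaussian_spectrum([], np.array([300.0])), [0.0])


class TestStabilityScenarios:
    def test_stable_noiseless_is_constant(self):
        truth = GroundTruth("stable", 0.0, (GaussianBand(350, 25, 0.5),), (),
                            c0=1.0, noise_sd=0.0, seed=0)
        s = simulate_stability_scenario(truth)
        assert np.all(s.absorbance == s.absorbance[0])

    def test_isosbestic_crossing_has_zero_temporal_variance(self):
        p, q = isosbestic_band_pair(lambda_star=340.0)
        truth = GroundTruth("isosbestic_degradation", 3e-4, (p,), (q,),
                            c0=1.0, noise_sd=0.0, seed=0)
        s = simulate_stability_scenario(truth)
        j = s.wavelength_index(340.0)
        sd = np.std(s.absorbance, axis=0)
        assert sd[j] == pytest.approx(0.0, abs=1e-14)
        assert np.max(np.abs(s.absorbance[-1] - s.absorbance[0])) > 0.05

    def test_plate_binding_scales_uniformly(self):
        k = 1e-4
        truth = GroundTruth("plate_binding", k, (GaussianBand(350, 25, 0.8),),
                            (), c0=1.0, noise_sd=0.0, seed=0)
        s = simulate_stability_scenario(truth)
        t0 = s.timepoints[0]
        for i, t in enumerate(s.timepoints):
            np.testing.assert_allclose(
                s.absorbance[i], math.exp(-k * (t - t0)) * s.absorbance[0],
                rtol=1e-12)

    def test_mole_conservation_pre_noise(self):
        """Parent + product concentrations sum to c0 at every timepoint."""
        p, q = isosbestic_band_pair()
        truth = GroundTruth("isosbestic_degradation", 2e-4, (p,), (q,),
                            c0=1.0, noise_sd=0.0, seed=0)
        s = simulate_stability_scenario(truth)
        wl = s.wavelengths
        eps = np.column_stack([gaussian_spectrum((p,), wl),
                               gaussian_spectrum((q,), wl)])
        # solve for the two concentrations at each timepoint
        conc, *_ = np.linalg.lstsq(eps, s.absorbance.T, rcond=None)
        np.testing.assert_allclose(conc.sum(axis=0), 1.0, rtol=1e-9)

    def test_wrong_scenario_rejected(self):
        truth = GroundTruth("pseudo_first_order", 1e-3,
                            (GaussianBand(350, 25, 0.5),), (), c0=1.0,
                            noise_sd=0.0, seed=0)
        with pytest.raises(ContractError):
            simulate_stability_scenario(truth)


class TestKineticsSeries:
    def test_noiseless_trace_is_exponential_with_embedded_kobs(self):
        """true_k2=10, [Cys]=5e-4 M embeds k_obs = 5e-3 s^-1 exactly.

        The noiseless trace at the most responsive wavelength must equal
        A_inf + (A0 - A_inf) e^(-k_obs t) pointwise; the affine map from
        e^(-k_obs t) to absorbance is pinned by two points and checked on
        all the others.
        """
        cfg = AssayConfig(dead_time=5.0, duration=2000.0)
        s = simulate_kinetics_series(10.0, 5e-5, [5e-4], cfg, seed=0,
                                     noise_sd=0.0)[0]
        j = s.wavelength_index(348.0)
        a = s.absorbance[:, j]
        e = np.exp(-(10.0 * 5e-4) * s.timepoints)
        c1 = (a[0] - a[-1]) / (e[0] - e[-1])
        c0 = a[0] - c1 * e[0]
        np.testing.assert_allclose(a, c0 + c1 * e, atol=1e-12)

    def test_second_order_near_pseudo_first_order_at_10x(self):
        """Exact second-order trace stays within 5% of the exponential."""
        cfg = AssayConfig(dead_time=5.0, duration=1000.0)
        comp, cys, k2 = 5e-5, 5e-4, 10.0
        pfo = simulate_kinetics_series(k2, comp, [cys], cfg, seed=0,
                                       noise_sd=0.0)[0]
        so = simulate_kinetics_series(k2, comp, [cys], cfg, seed=0,
                                      noise_sd=0.0, mode="second_order")[0]
        j = pfo.wavelength_index(348.0)

        # independent oracle: numerical ODE integration of the exact law
        def rhs(t, y):
            b, a = y
            return [-k2 * a * b, -k2 * a * b]

        sol = solve_ivp(rhs, (0, cfg.duration), [comp, cys],
                        t_eval=pfo.timepoints, rtol=1e-10, atol=1e-16)
        parent_ode = sol.y[0]
        # absorbance is affine in the parent concentration; fit the two
        # coefficients by least squares and require a negligible residual
        design = np.column_stack([np.ones_like(parent_ode), parent_ode])
        coef, *_ = np.linalg.lstsq(design, so.absorbance[:, j], rcond=None)
        resid = so.absorbance[:, j] - design @ coef
        assert np.max(np.abs(resid)) < 1e-6 * np.max(so.absorbance[:, j])
        # implied parent fractions: second-order vs pseudo-first-order
        frac_so = parent_ode / comp
        frac_pfo = np.exp(-k2 * cys * pfo.timepoints)
        assert np.max(np.abs(frac_so - frac_pfo)) < 0.05

    def test_low_excess_rejected_without_flag(self):
        with pytest.raises(ContractError, match="10x excess"):
            simulate_kinetics_series(10.0, 5e-5, [1e-4], seed=0)

    def test_empty_concentration_list_rejected(self):
        with pytest.raises(ContractError):
            simulate_kinetics_series(10.0, 5e-5, [], seed=0)


class TestDeterminism:
    def test_same_seed_bit_identical_different_seed_not(self):
        truth = GroundTruth("stable", 0.0, (GaussianBand(350, 25, 0.5),), (),
                            c0=1.0, noise_sd=0.003, seed=42)
        a = simulate_stability_scenario(truth)
        b = simulate_stability_scenario(truth)
        assert np.array_equal(a.absorbance, b.absorbance)
        truth2 = GroundTruth("stable", 0.0, (GaussianBand(350, 25, 0.5),), (),
                             c0=1.0, noise_sd=0.003, seed=43)
        c = simulate_stability_scenario(truth2)
        assert not np.array_equal(a.absorbance, c.absorbance)
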