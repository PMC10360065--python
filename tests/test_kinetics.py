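"""Decay fitting, k2 estimation by both routes, second-order conversion."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from cbxscreen.config import AssayConfig
from cbxscreen.errors import ContractError
from cbxscreen.kinetics import (
    fit_one_phase_decay,
    k2_from_regression,
    k2_from_single,
    second_order_conversion,
)
from cbxscreen.simulate import simulate_kinetics_series
from cbxscreen.stability import most_responsive_wavelength


def _decay(times, a0, plateau, k):
    return plateau + (a0 - plateau) * np.exp(-k * np.asarray(times))


class TestOnePhaseDecayFit:
    def test_noiseless_recovery_to_machine_precision(self):
        t = np.linspace(0, 14400, 49)
        y = _decay(t, 0.60, 0.10, 2e-3)
        fit = fit_one_phase_decay(t, y)
        assert fit.converged
        assert fit.k_obs == pytest.approx(2e-3, rel=1e-6)
        assert fit.a0 == pytest.approx(0.60, rel=1e-6)
        assert fit.plateau == pytest.approx(0.10, rel=1e-6)

    def test_constant_signal_not_converged(self):
        t = np.linspace(0, 1000, 20)
        fit = fit_one_phase_decay(t, np.full(20, 0.5))
        assert not fit.converged
        assert abs(fit.span) < 1e-3

    def test_noisy_recovery_within_5pct(self):
        t = np.linspace(180, 14400, 49)
        rng = np.random.default_rng(7)
        y = _decay(t, 0.60, 0.10, 2e-3) + rng.normal(0, 0.003, t.size)
        fit = fit_one_phase_decay(t, y)
        assert fit.converged
        assert fit.k_obs == pytest.approx(2e-3, rel=0.05)

    def test_hyperreactive_yields_bound_not_estimate(self):
        t = np.linspace(180, 14400, 49)
        y = _decay(t, 0.60, 0.10, 0.05)  # half-life 14 s, flat by first read
        fit = fit_one_phase_decay(t, y)
        assert not fit.converged
        if fit.k_obs_lower_bound is not None:
            assert fit.k_obs_lower_bound == pytest.approx(
                -math.log(0.05) / 180.0, rel=1e-6)

    def test_contract_violations(self):
        with pytest.raises(ContractError):
            fit_one_phase_decay([0, 1, 2, 3], [1, 1, 1, 1])
        with pytest.raises(ContractError):
            fit_one_phase_decay([0, 2, 1, 3, 4], [1, 1, 1, 1, 1])

    def test_fixed_plateau_respected(self):
        t = np.linspace(0, 10000, 30)
        y = _decay(t, 0.60, 0.10, 5e-4)
        fit = fit_one_phase_decay(t, y, fixed_plateau=0.10)
        assert fit.plateau == 0.10
        assert fit.k_obs == pytest.approx(5e-4, rel=1e-6)


class TestK2Routes:
    def test_single_concentration_arithmetic(self):
        est = k2_from_single(5.0e-3, 5.0e-4)
        assert est.k2 == pytest.approx(10.0)
        assert est.method == "single_conc" and est.n_points == 1
        assert k2_from_single(1e-3, 1.0).k2 == pytest.approx(1e-3)

    def test_single_concentration_guards(self):
        with pytest.raises(ContractError):
            k2_from_single(0.0, 1e-4)
        with pytest.raises(ContractError):
            k2_from_single(1e-3, -1.0)

    def test_regression_on_collinear_points(self):
        est = k2_from_regression([(1e-4, 1e-3), (2e-4, 2e-3), (5e-4, 5e-3)])
        assert est.k2 == pytest.approx(10.0)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)
        assert est.r_squared == pytest.approx(1.0)

    def test_affine_shift_moves_intercept_not_slope(self):
        pts = [(1e-4, 1e-3 + 1e-5), (2e-4, 2e-3 + 1e-5), (5e-4, 5e-3 + 1e-5)]
        est = k2_from_regression(pts)
        assert est.k2 == pytest.approx(10.0)
        assert est.intercept == pytest.approx(1e-5, rel=1e-6)

    def test_regression_guards(self):
        with pytest.raises(ContractError):
            k2_from_regression([(1e-4, 1e-3), (2e-4, 2e-3)])
        with pytest.raises(ContractError):
            k2_from_regression([(1e-4, 1e-3)] * 5)

    def test_regression_matches_single_on_collinear_input(self):
        pts = [(c, 10.0 * c) for c in (1e-4, 3e-4, 1e-3)]
        est = k2_from_regression(pts)
        for c, k in pts:
            assert k2_from_single(k, c).k2 == pytest.approx(est.k2)

    def test_end_to_end_noiseless_recovery(self):
        """Simulated series -> decay fits -> regression recovers planted k2."""
        cfg = AssayConfig(dead_time=5.0, duration=4000.0)
        cys = [5e-4, 1e-3, 1.5e-3, 2e-3, 2.5e-3, 3e-3, 3.5e-3]
        series = simulate_kinetics_series(10.0, 5e-5, cys, cfg, seed=0,
                                          noise_sd=0.0)
        pairs = []
        for s, c in zip(series, cys):
            lam = most_responsive_wavelength(s)
            j = s.wavelength_index(lam)
            fit = fit_one_phase_decay(s.timepoints, s.absorbance[:, j], cfg)
            assert fit.converged
            pairs.append((c, fit.k_obs))
            assert k2_from_single(fit.k_obs, c).k2 == pytest.approx(
                10.0, rel=1e-6)
        assert k2_from_regression(pairs).k2 == pytest.approx(10.0, rel=1e-6)


class TestSecondOrderConversion:
    def test_equal_concentration_closed_form(self):
        # x/c = ckt/(1+ckt) = 0.9/1.9
        assert second_order_conversion(10.0, 5e-5, 5e-5, 1800.0) == \
            pytest.approx(0.9 / 1.9)

    def test_two_equivalents_against_ode_oracle(self):
        got = second_order_conversion(10.0, 5e-5, 2.5e-5, 1800.0)
        sol = solve_ivp(lambda t, x: 10.0 * (5e-5 - x[0]) * (2.5e-5 - x[0]),
                        (0, 1800.0), [0.0], rtol=1e-11, atol=1e-16)
        assert got == pytest.approx(sol.y[0, -1] / 2.5e-5, rel=1e-7)
        assert got == pytest.approx(0.53, abs=0.01)

    def test_short_time_limit_is_zero(self):
        assert second_order_conversion(10.0, 5e-5, 2.5e-5, 1e-9) == \
            pytest.approx(0.0, abs=1e-10)

    def test_guards(self):
        with pytest.raises(ContractError):
            second_order_conversion(0.0, 1e-4, 1e-4, 10.0)
        with pytest.raises(ContractError):
            second_order_conversion(1.0, 1e-4, 1e-4, -1.0)

    @given(k2=st.floats(0.1, 100), t=st.floats(1, 1e5),
           a0=st.floats(1e-6, 1e-3), b0=st.floats(1e-6, 1e-3))
    def test_bounded_in_unit_interval(self, k2, t, a0, b0):
        x = second_order_conversion(k2, a0, b0, t)
        assert 0.0 <= x < 1.0

    def test_strictly_increasing_in_each_argument(self):
        base = dict(k2=5.0, a0=5e-5, b0=2.5e-5, t=600.0)
        x0 = second_order_conversion(**base)
        for key, factor in (("k2", 1.5), ("t", 1.5), ("a0", 1.5)):
            bumped = dict(base)
            bumped[key] = base[key] * factor
            assert second_order_conversion(**bumped) > x0


class TestPseudoFirstOrderValidity:
    def test_error_small_at_10x_and_grows_below(self):
        """Fitting an exact second-order trace: <=10% error at 10x excess,
        monotone growth as the excess drops toward 2x."""
        k2, comp = 10.0, 5e-5
        errs = []
        for ratio in (10, 6, 4, 2):
            cys = ratio * comp
            nominal = k2 * cys
            dur = 6.0 / nominal
            cfg = AssayConfig(dead_time=0.02 * dur, duration=dur)
            s = simulate_kinetics_series(
                k2, comp, [cys], cfg, seed=0, mode="second_order",
                noise_sd=0.0, allow_low_excess=True)[0]
            j = s.wavelength_index(348.0)
            fit = fit_one_phase_decay(s.timepoints, s.absorbance[:, j], cfg)
            errs.append(abs(fit.k_obs - nominal) / nominal)
        assert errs[0] <= 0.10
        assert all(e1 < e2 for e1, e2 in zip(errs, errs[1:]))
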