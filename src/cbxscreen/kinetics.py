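"""Rate-constant estimation for the nitrile + cysteine click reaction.

Under pseudo-first-order conditions (cysteine in >= 10-fold excess) the
compound's absorbance at its most responsive wavelength relaxes as a single
exponential, A(t) = plateau + (A0 - plateau) e^(-k_obs t).  The second-order
rate constant k2 follows either from one concentration (k2 = k_obs/[Cys])
or, more robustly, as the slope of k_obs against [Cys] over several
concentrations.  For planning labeling experiments, the exact second-order
progress law gives the conversion of the limiting species at any time.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from lmfit import Model
from scipy import stats

from .config import DEFAULT_CONFIG, AssayConfig
from .errors import ContractError
from .types import DecayFit, K2Estimate

#: Fitted-model completion at the first read above which a decay is treated
#: as hyperreactive and only a lower bound on k_obs is reported.
HYPERREACTIVE_FRACTION = 0.95


def _one_phase(t, a0, plateau, k_obs):
    return plateau + (a0 - plateau) * np.exp(-k_obs * t)


def _initial_guesses(times: np.ndarray, signal: np.ndarray):
    plateau0 = float(signal[-1])
    a00 = float(signal[0])
    resid = signal - plateau0
    s0 = resid[0]
    k0 = None
    if abs(s0) > 0:
        # log-linear transform of the baseline-subtracted signal
        usable = (np.sign(resid) == np.sign(s0)) & (np.abs(resid) > 0.05 * abs(s0))
        if usable.sum() >= 3:
            slope, intercept = np.polyfit(times[usable],
                                          np.log(np.abs(resid[usable])), 1)
            if slope < 0:
                k0 = -slope
                a00 = plateau0 + np.sign(s0) * math.exp(
                    intercept)  # extrapolate to t=0
    if k0 is None or not np.isfinite(k0) or k0 <= 0:
        k0 = 3.0 / max(times[-1] - times[0], 1e-9)
    return a00, plateau0, k0


def fit_one_phase_decay(times: Sequence[float], signal: Sequence[float],
                        config: AssayConfig = DEFAULT_CONFIG,
                        fixed_plateau: Optional[float] = None) -> DecayFit:
    """Least-squares fit of a one-phase decay with positive rate.

    The three parameters are the extrapolated t=0 absorbance, the plateau
    (optionally fixed to a blank value), and k_obs > 0.  Failure to
    converge — including a span indistinguishable from noise, or a
    reaction already >95% complete at the first read — is reported through
    ``converged=False``, never an exception.  Hyperreactive fits carry the
    lower bound k_obs >= -ln(0.05)/t_first instead of a point estimate.
    """
    times = np.asarray(times, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if times.size < 5:
        raise ContractError("need at least 5 timepoints for a decay fit")
    if times.size != signal.size:
        raise ContractError("times and signal must have equal length")
    if np.any(np.diff(times) <= 0):
        raise ContractError("times must be strictly increasing")

    a00, plateau0, k0 = _initial_guesses(times, signal)
    model = Model(_one_phase)
    params = model.make_params(a0=a00, plateau=plateau0, k_obs=k0)
    params["k_obs"].set(min=1e-12)
    if fixed_plateau is not None:
        params["plateau"].set(value=float(fixed_plateau), vary=False)
    try:
        result = model.fit(signal, params, t=times)
        ok = bool(result.success)
        a0 = float(result.params["a0"].value)
        plateau = float(result.params["plateau"].value)
        k_obs = float(result.params["k_obs"].value)
        rms = float(np.sqrt(np.mean(result.residual ** 2)))
    except Exception:
        ok, a0, plateau, k_obs = False, a00, plateau0, k0
        rms = float(np.std(signal))

    span = a0 - plateau
    # span below noise: the data carry no decay to fit
    if abs(span) < max(3.0 * rms, 1e-6):
        ok = False
    frac_first = 1.0 - math.exp(-k_obs * times[0]) if times[0] > 0 else 0.0
    bound = None
    if ok and frac_first > HYPERREACTIVE_FRACTION:
        # reaction essentially over before the first read; only a bound holds
        ok = False
        bound = -math.log(1.0 - HYPERREACTIVE_FRACTION) / times[0]
    return DecayFit(a0=a0, plateau=plateau, k_obs=k_obs, rms_residual=rms,
                    converged=ok, fraction_complete_at_first_read=frac_first,
                    k_obs_lower_bound=bound)


def k2_from_single(k_obs: float, cys_conc: float) -> K2Estimate:
    """k2 = k_obs / [Cys] from a single pseudo-first-order experiment."""
    if k_obs <= 0 or cys_conc <= 0:
        raise ContractError("k_obs and cys_conc must be positive")
    return K2Estimate(k2=k_obs / cys_conc, method="single_conc", n_points=1)


def k2_from_regression(pairs: Sequence[tuple[float, float]]) -> K2Estimate:
    """k2 as the OLS slope of k_obs against [Cys] (intercept free).

    Requires at least three distinct cysteine concentrations.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ContractError("need >= 3 (cys_conc, k_obs) points")
    concs = np.array([p[0] for p in pairs], dtype=float)
    kobs = np.array([p[1] for p in pairs], dtype=float)
    if np.unique(concs).size < 3:
        raise ContractError("need >= 3 distinct cysteine concentrations")
    fit = stats.linregress(concs, kobs)
    if fit.slope <= 0:
        raise ContractError("regression slope is nonpositive; no k2 estimate")
    return K2Estimate(k2=float(fit.slope), method="multi_conc_slope",
                      n_points=len(pairs), intercept=float(fit.intercept),
                      r_squared=float(fit.rvalue ** 2))


def second_order_conversion(k2: float, a0: float, b0: float, t: float) -> float:
    """Conversion of the limiting species under exact second-order kinetics.

    Closed-form solution of dx/dt = k2 (a0 - x)(b0 - x) with a0 the excess
    and b0 the limiting concentration (molar); returns x(t)/b0 in [0, 1).
    """
    if k2 <= 0 or a0 <= 0 or b0 <= 0 or t <= 0:
        raise ContractError("k2, concentrations and time must be positive")
    if math.isclose(a0, b0, rel_tol=1e-9):
        ckt = a0 * k2 * t
        return ckt / (1.0 + ckt)
    d = a0 - b0
    if d > 0:
        # overflow-safe: divide through by E = e^(d k2 t)
        em = math.exp(-d * k2 * t)
        frac = a0 * (1.0 - em) / (a0 - b0 * em)
    else:
        E = math.exp(d * k2 * t)  # in (0, 1)
        frac = a0 * (E - 1.0) / (a0 * E - b0) / 1.0
    return min(frac, 1.0 - 1e-16)


def pseudo_first_order_kobs(k2: float, cys_conc: float) -> float:
    """k_obs implied by k2 at a fixed cysteine concentration."""
    if k2 <= 0 or cys_conc <= 0:
        raise ContractError("k2 and cys_conc must be positive")
    return k2 * cys_conc
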