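"""Buffer-stability classification from spectral time series.

A compound's stability over the 4 h monitoring window is summarized by a
single statistic: the relative absorbance difference between the first
read and the end of the window, evaluated at the most responsive
wavelength.  Cut points at 0.1 and 0.2 (set from repeatability
experiments) partition compounds into stable / intermediate / unstable.
For non-stable compounds, two mechanisms are distinguished: chemical
degradation, which interconverts two chromophores and therefore shows an
isosbestic point, and plate-wall binding, which removes compound from
solution and scales the whole spectrum uniformly with no crossing.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .config import DEFAULT_CONFIG, AssayConfig
from .errors import ContractError, DivisionGuardError, NoSignalError
from .types import PlateWell, SpectralTimeSeries, StabilityResult


def most_responsive_wavelength(series: SpectralTimeSeries,
                               top_k: int = 1) -> float | list[float]:
    """Wavelength with the largest |A(t_last) - A(t_first)|.

    Ties break toward the longer wavelength.  ``top_k > 1`` returns the
    top-k list (diagnostics).  A perfectly flat series has no responsive
    wavelength and raises :class:`NoSignalError`.
    """
    change = np.abs(series.absorbance[-1] - series.absorbance[0])
    if np.all(change == 0):
        raise NoSignalError(
            f"series {series.well_id!r} shows no spectral change")
    # stable argsort on the reversed grid puts the longer wavelength first
    # among exact ties
    order = np.argsort(-change[::-1], kind="stable")
    idx = [series.wavelengths.size - 1 - int(i) for i in order[:top_k]]
    if top_k == 1:
        return float(series.wavelengths[idx[0]])
    return [float(series.wavelengths[i]) for i in idx]


def relative_difference(series: SpectralTimeSeries, wavelength: float,
                        config: AssayConfig = DEFAULT_CONFIG,
                        ) -> tuple[float, float, bool]:
    """(abs_diff, rel_diff, low_signal_flag) at one wavelength.

    abs_diff = |A(t_last) - A(t_first)|; rel_diff divides by the
    first-read absorbance.  The low-signal flag marks first-read
    absorbance below ``config.min_first_absorbance``, where the ratio is
    dominated by noise.  A nonpositive first-read absorbance cannot
    normalize anything and raises :class:`DivisionGuardError`.
    """
    j = series.wavelength_index(wavelength)
    a_first = float(series.absorbance[0, j])
    a_last = float(series.absorbance[-1, j])
    if a_first <= 0:
        raise DivisionGuardError(
            f"first-read absorbance {a_first:.4g} AU at {wavelength} nm is "
            "nonpositive")
    abs_diff = abs(a_last - a_first)
    return abs_diff, abs_diff / a_first, a_first < config.min_first_absorbance


def classify_stability(rel_diff: float,
                       config: AssayConfig = DEFAULT_CONFIG) -> str:
    """Map a relative absorbance difference to its stability class.

    Below ``stable_threshold`` (0.1): stable; above ``unstable_threshold``
    (0.2): unstable; both boundaries inclusive into intermediate.
    """
    if not np.isfinite(rel_diff) or rel_diff < 0:
        raise ContractError(f"rel_diff must be finite and >= 0, got {rel_diff}")
    if rel_diff < config.stable_threshold:
        return "stable"
    if rel_diff <= config.unstable_threshold:
        return "intermediate"
    return "unstable"


def estimate_noise_sd(series: SpectralTimeSeries) -> float:
    """Noise floor from first differences of the flattest wavelengths.

    Successive-timepoint differences at the decile of wavelengths with the
    smallest total change are dominated by measurement noise; their
    standard deviation over sqrt(2) estimates the per-cell noise sd.
    """
    total_change = np.abs(series.absorbance[-1] - series.absorbance[0])
    n_keep = max(1, series.n_wavelengths // 10)
    flattest = np.argsort(total_change, kind="stable")[:n_keep]
    diffs = np.diff(series.absorbance[:, flattest], axis=0)
    return float(np.std(diffs) / np.sqrt(2.0))


def _proportionality_residual(series: SpectralTimeSeries) -> float:
    """Worst relative residual of per-timepoint uniform-scaling fits.

    Each timepoint spectrum is regressed on the first-read spectrum by a
    least-squares scale factor; plate binding leaves only noise behind.
    """
    ref = series.absorbance[0]
    denom = float(ref @ ref)
    if denom == 0:
        return np.inf
    ref_norm = float(np.linalg.norm(ref))
    worst = 0.0
    for t in range(1, series.n_times):
        row = series.absorbance[t]
        scale = float(row @ ref) / denom
        resid = np.linalg.norm(row - scale * ref)
        worst = max(worst, resid / ref_norm)
    return worst


#: Relative residual below which timepoint spectra count as mutually
#: proportional (uniform scaling, i.e. plate binding).
PROPORTIONALITY_TOL = 0.02

#: Multiplier on the estimated noise sd for the isosbestic (zero temporal
#: variance) wavelength test.
ISOSBESTIC_SD_FACTOR = 3.0


def classify_mechanism(series: SpectralTimeSeries,
                       config: AssayConfig = DEFAULT_CONFIG) -> str:
    """Diagnose why a non-stable series changes: degradation vs binding.

    Plate binding: all timepoint spectra proportional to the first
    (uniform-scaling fit, relative residual below 2% or below the
    residual the noise floor itself produces, whichever is larger).
    Isosbestic degradation: spectra are NOT mutually proportional, the
    overall change exceeds the unstable threshold, and some informative
    wavelength (one carrying real absorbance) has temporal standard
    deviation below a noise-scaled tolerance — the crossing point of the
    two chromophores.  Anything else is undetermined.
    """
    try:
        lam = _screen_wavelength(series, config)
        _, rel, _ = relative_difference(series, lam, config)
    except (NoSignalError, DivisionGuardError):
        return "undetermined"
    if rel < config.stable_threshold:
        return "undetermined"  # nothing changed; no mechanism to diagnose
    sd_est = estimate_noise_sd(series)
    ref_norm = float(np.linalg.norm(series.absorbance[0]))
    # pure noise contributes ~ sd * sqrt(2W) to each per-timepoint residual
    noise_floor = 3.0 * sd_est * np.sqrt(2.0 * series.n_wavelengths) \
        / max(ref_norm, 1e-12)
    prop_tol = max(PROPORTIONALITY_TOL, noise_floor)
    if _proportionality_residual(series) < prop_tol:
        return "plate_binding"
    if rel <= config.unstable_threshold:
        return "undetermined"
    sd_tol = ISOSBESTIC_SD_FACTOR * sd_est + 1e-9
    temporal_sd = np.std(series.absorbance, axis=0)
    informative = series.absorbance[0] >= config.min_first_absorbance
    if np.any(temporal_sd[informative] < sd_tol):
        return "isosbestic_degradation"
    return "undetermined"


def screen_stability(wells: Sequence[PlateWell],
                     config: AssayConfig = DEFAULT_CONFIG,
                     ) -> list[StabilityResult]:
    """Run the full stability screen on compound-in-buffer wells.

    Wells with a reagent (other than none) or without a compound are
    skipped — they belong to the reactivity screen.
    """
    results = []
    for w in wells:
        cond = w.condition
        if cond.compound_id is None or cond.reagent != "none":
            continue
        results.append(stability_result(w.series, config))
    return results


def _screen_wavelength(series: SpectralTimeSeries,
                       config: AssayConfig) -> float:
    """Most responsive wavelength among those with a usable baseline.

    The relative statistic divides by the first-read absorbance, so the
    screen only considers wavelengths where that baseline is at least
    ``min_first_absorbance``; without any such wavelength the unrestricted
    argmax is used (the result then carries the low-signal flag).
    """
    informative = series.absorbance[0] >= config.min_first_absorbance
    if not np.any(informative):
        return most_responsive_wavelength(series)
    change = np.abs(series.absorbance[-1] - series.absorbance[0])
    change = np.where(informative, change, -np.inf)
    if np.all(change[informative] == 0):
        raise NoSignalError(
            f"series {series.well_id!r} shows no spectral change")
    order = np.argsort(-change[::-1], kind="stable")
    return float(series.wavelengths[series.wavelengths.size - 1 - int(order[0])])


def stability_result(series: SpectralTimeSeries,
                     config: AssayConfig = DEFAULT_CONFIG) -> StabilityResult:
    """Classify one series, attaching the mechanism for non-stable calls."""
    try:
        lam = _screen_wavelength(series, config)
        abs_diff, rel_diff, low_signal = relative_difference(
            series, lam, config)
    except NoSignalError:
        # perfectly flat: stable by definition, no responsive wavelength
        lam = float(series.wavelengths[-1])
        abs_diff, rel_diff = 0.0, 0.0
        low_signal = series.absorbance[0, -1] < config.min_first_absorbance
    except DivisionGuardError:
        # no informative wavelength at all: noise-floor well
        lam = float(series.wavelengths[-1])
        abs_diff, rel_diff = 0.0, 0.0
        low_signal = True
    cls = classify_stability(rel_diff, config)
    mech = "none" if cls == "stable" else classify_mechanism(series, config)
    return StabilityResult(
        compound_id=series.compound_id or series.well_id, lambda_star=lam,
        abs_diff=abs_diff, rel_diff=rel_diff, stability_class=cls,
        mechanism=mech, low_signal_flag=low_signal)
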