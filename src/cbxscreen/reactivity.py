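"""Reactivity flagging against reagent blanks, and hyperreactivity.

A compound-reagent pair is reactive when the blank-subtracted series
changes by more than the reactivity threshold (relative absorbance
difference > 0.2) over the monitoring window.  Hyperreactive compounds
finish reacting inside the ~3 min instrument dead time, so their first
spectrum already differs from the compound-alone reference.  The Ellman's
reagent (reduced DTNB) readout is the release of the 5-mercapto-2-
nitrobenzoate chromophore and is evaluated at a fixed 412 nm instead of
the argmax wavelength.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, AssayConfig
from .errors import AlignmentError, DivisionGuardError, NoSignalError
from .io import find_blank
from .stability import most_responsive_wavelength, relative_difference
from .types import PlateWell, ReactivityCall, SpectralTimeSeries

DTNB_WAVELENGTH = 412.0


def _check_grids(a: SpectralTimeSeries, b: SpectralTimeSeries,
                 cadence_tol: Optional[float] = None) -> None:
    if a.n_wavelengths != b.n_wavelengths or \
            not np.allclose(a.wavelengths, b.wavelengths):
        raise AlignmentError("sample and blank wavelength grids differ")
    if a.n_times != b.n_times:
        raise AlignmentError("sample and blank timepoint counts differ")
    if cadence_tol is None:
        cadence_tol = float(np.median(np.diff(a.timepoints)))
    if np.any(np.abs(a.timepoints - b.timepoints) > cadence_tol):
        raise AlignmentError(
            "sample and blank timepoints differ by more than one cadence step")


def _blank_subtract(sample: SpectralTimeSeries,
                    blank: SpectralTimeSeries) -> SpectralTimeSeries:
    _check_grids(sample, blank)
    return SpectralTimeSeries(
        well_id=sample.well_id, compound_id=sample.compound_id,
        timepoints=sample.timepoints, wavelengths=sample.wavelengths,
        absorbance=sample.absorbance - blank.absorbance)


def flag_reactivity(sample: SpectralTimeSeries, blank: SpectralTimeSeries,
                    config: AssayConfig = DEFAULT_CONFIG,
                    reagent: str = "none",
                    compound_reference: Optional[SpectralTimeSeries] = None,
                    ) -> ReactivityCall:
    """Flag a compound-reagent pair by its blank-subtracted change.

    The blank is the reagent-only trace on the same grid.  For
    ``reagent='DTNB_reduced'`` the statistic is evaluated at 412 nm; for
    every other reagent at the most responsive wavelength of the
    subtracted series.  When a compound-alone reference is supplied the
    call also screens for hyperreactivity at the first read.
    """
    diff = _blank_subtract(sample, blank)
    try:
        if reagent == "DTNB_reduced":
            lam = DTNB_WAVELENGTH
        else:
            lam = most_responsive_wavelength(diff)
        _, rel, _ = relative_difference(diff, lam, config)
    except (NoSignalError, DivisionGuardError):
        rel = 0.0
    hyper = False
    if compound_reference is not None:
        hyper = detect_hyperreactive(sample, compound_reference, config,
                                     blank=blank)
    return ReactivityCall(
        compound_id=sample.compound_id or sample.well_id, reagent=reagent,
        rel_diff_vs_blank=rel, reactive=(rel > config.reactivity_threshold)
        or hyper, hyperreactive=hyper)


def detect_hyperreactive(sample: SpectralTimeSeries,
                         compound_reference: SpectralTimeSeries,
                         config: AssayConfig = DEFAULT_CONFIG,
                         blank: Optional[SpectralTimeSeries] = None) -> bool:
    """True when the first read already differs from the compound-alone trace.

    The comparison happens at the wavelength where the first-read spectra
    differ most; the relative difference against the reference first-read
    absorbance must exceed the reactivity threshold.  An optional
    reagent-only blank is subtracted from the sample first.
    """
    ref = compound_reference
    _check_grids(sample, ref)
    first = sample.absorbance[0].copy()
    if blank is not None:
        _check_grids(sample, blank)
        first = first - blank.absorbance[0]
    delta = np.abs(first - ref.absorbance[0])
    informative = ref.absorbance[0] >= config.min_first_absorbance
    if not np.any(informative):
        return False
    masked = np.where(informative, delta, -np.inf)
    j = int(np.argmax(masked[::-1]))
    j = sample.n_wavelengths - 1 - j
    return delta[j] / ref.absorbance[0, j] > config.reactivity_threshold


def screen_reactivity(wells: Sequence[PlateWell],
                      config: AssayConfig = DEFAULT_CONFIG,
                      ) -> list[ReactivityCall]:
    """Run the reactivity screen across a plate.

    Sample wells (compound + reagent) are matched to reagent-only blanks
    by (reagent, replicate); compound-alone wells (reagent 'none') of the
    same compound serve as the hyperreactivity reference.
    """
    references = {
        (w.condition.compound_id, w.condition.replicate): w.series
        for w in wells
        if w.condition.compound_id is not None and w.condition.reagent == "none"
    }
    calls = []
    for w in wells:
        cond = w.condition
        if cond.compound_id is None or cond.reagent == "none":
            continue
        blank = find_blank(wells, cond.reagent, cond.replicate)
        if blank is None:
            raise AlignmentError(
                f"no {cond.reagent!r} blank for replicate {cond.replicate}")
        ref = references.get((cond.compound_id, cond.replicate))
        calls.append(flag_reactivity(w.series, blank.series, config,
                                     reagent=cond.reagent,
                                     compound_reference=ref))
    return calls
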