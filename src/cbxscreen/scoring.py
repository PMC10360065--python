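"""Global reactivity/selectivity/derivatization score and the
reactivity-selectivity correlation.

The composite score summarizes three orthogonal desiderata of a
bioconjugation electrophile: how fast it labels an N-terminal cysteine
(reactivity), how little it touches peptides without one (selectivity),
and whether its substituent offers a handle for further derivatization.
The exact weighting is a policy choice; the default formula below is
labeled in every output so alternative component definitions stay
pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ContractError, UndefinedCorrelationError
from .types import CompoundRecord, GlobalScore

#: k2 (s^-1 M^-1) above which labeling completes within 30 min at low
#: micromolar concentration; used as the reactivity normalization pivot
#: when no conversion data are available.
K2_COMPLETE_LABELING = 5.0

FORMULA_ID = "default-v1"


def global_score(record: CompoundRecord,
                 k2: float,
                 up1_conversion: Optional[float] = None,
                 up2_conversion: float = 0.0,
                 weights: tuple = (1.0, 1.0, 1.0)) -> GlobalScore:
    """Score one compound from its kinetics, labeling and scaffold.

    Components (each in [0, 1]):
    reactivity = UP1 conversion / 100 when measured, else min(k2 / 5, 1);
    selectivity = 1 - UP2 conversion / 100;
    derivatization = 1 for NH2 / OH / CO2H substituents, else 0.
    Total = weighted sum (default unit weights, range [0, 3]).
    """
    if k2 <= 0:
        raise ContractError("k2 must be positive")
    for name, conv in (("up1_conversion", up1_conversion),
                       ("up2_conversion", up2_conversion)):
        if conv is not None and not (0.0 <= conv <= 100.0):
            raise ContractError(f"{name} out of [0, 100]: {conv}")
    if len(weights) != 3 or any(w < 0 for w in weights):
        raise ContractError("weights must be three nonnegative numbers")
    if up1_conversion is not None:
        reactivity = up1_conversion / 100.0
    else:
        reactivity = min(k2 / K2_COMPLETE_LABELING, 1.0)
    selectivity = 1.0 - up2_conversion / 100.0
    derivatization = 1.0 if record.derivatizable else 0.0
    total = (weights[0] * reactivity + weights[1] * selectivity
             + weights[2] * derivatization)
    return GlobalScore(
        compound_id=record.compound_id, reactivity_component=reactivity,
        selectivity_component=selectivity,
        derivatization_component=derivatization, total=total,
        weights=tuple(weights), formula_id=FORMULA_ID)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of UP2 conversion against log10 k2, with trend."""

    r_log: float
    r_raw: float
    slope: float        # conversion points per decade of k2
    intercept: float
    n_points: int


def reactivity_selectivity_correlation(
        points: Sequence[tuple[float, float]]) -> CorrelationResult:
    """Correlate k2 (log scale) with UP2 conversion across a cohort.

    More reactive electrophiles label the control peptide (no N-terminal
    cysteine) more — the reactivity/selectivity trade-off.  Requires at
    least three points, nonconstant in both coordinates; k2 spans orders
    of magnitude, hence the log10 axis for the primary statistic.
    """
    points = list(points)
    if len(points) < 3:
        raise ContractError("need at least 3 (k2, conversion) points")
    k2 = np.array([p[0] for p in points], dtype=float)
    conv = np.array([p[1] for p in points], dtype=float)
    if np.any(k2 <= 0):
        raise ContractError("k2 values must be positive")
    if np.ptp(k2) == 0 or np.ptp(conv) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined for a constant coordinate")
    logk = np.log10(k2)
    r_log = float(stats.pearsonr(logk, conv).statistic)
    r_raw = float(stats.pearsonr(k2, conv).statistic)
    line = stats.linregress(logk, conv)
    return CorrelationResult(r_log=r_log, r_raw=r_raw,
                             slope=float(line.slope),
                             intercept=float(line.intercept),
                             n_points=len(points))
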