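"""Core data model for plate experiments and screen results.

Internal unit conventions: time in seconds, concentrations in molar,
wavelengths in nanometers, absorbance in AU.  Micromolar and minutes are
accepted at file interfaces and converted on ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ContractError

REAGENTS = ("none", "Lys", "Ser", "TCEP", "NAC", "Cys", "DTNB_reduced", "peptide")

STABILITY_CLASSES = ("stable", "intermediate", "unstable")
MECHANISMS = ("none", "isosbestic_degradation", "plate_binding", "undetermined")


@dataclass
class SpectralTimeSeries:
    """Absorbance of one well on a (time x wavelength) grid.

    ``timepoints`` are seconds since mixing (the first entry reflects the
    instrument dead time), strictly ascending, length T >= 2.
    ``wavelengths`` are nanometers, strictly ascending, length W >= 1.
    ``absorbance`` is the T x W grid in AU; every cell must be finite —
    gaps are an ingestion error, never silently filled.
    """

    well_id: str
    compound_id: Optional[str]
    timepoints: np.ndarray
    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.timepoints.ndim != 1 or self.timepoints.size < 2:
            raise ContractError("need at least two timepoints")
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 1:
            raise ContractError("need at least one wavelength")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ContractError("timepoints must be strictly ascending")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ContractError("wavelengths must be strictly ascending")
        if self.timepoints[0] < 0:
            raise ContractError("timepoints must be nonnegative")
        expected = (self.timepoints.size, self.wavelengths.size)
        if self.absorbance.shape != expected:
            raise ContractError(
                f"absorbance grid {self.absorbance.shape} != {expected}")
        if not np.all(np.isfinite(self.absorbance)):
            raise ContractError("absorbance contains non-finite values")

    @property
    def n_times(self) -> int:
        return self.timepoints.size

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def wavelength_index(self, wavelength: float) -> int:
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[idx] - wavelength) > 1e-6:
            raise ContractError(f"wavelength {wavelength} nm not on the grid")
        return idx


@dataclass(frozen=True)
class WellCondition:
    """What was in a well: compound, reagent, concentrations (molar)."""

    compound_id: Optional[str]
    compound_conc: float
    reagent: str
    reagent_conc: float
    replicate: int = 1
    is_blank: bool = False

    def __post_init__(self) -> None:
        if self.reagent not in REAGENTS:
            raise ContractError(f"unknown reagent {self.reagent!r}")
        if self.reagent == "none" and self.reagent_conc != 0:
            raise ContractError("reagent 'none' requires reagent_conc == 0")
        if self.replicate < 1:
            raise ContractError("replicate must be a positive integer")
        if self.is_blank and self.compound_id is not None:
            raise ContractError("a blank well has no compound")

    @property
    def pseudo_first_order_ok(self) -> bool:
        """True when the reagent is in >= 10-fold excess over the compound.

        Violations are flagged by callers, not rejected: the condition is a
        validity requirement for pseudo-first-order analysis, not for the
        well itself.
        """
        if self.compound_conc <= 0:
            return True
        return self.reagent_conc >= 10.0 * self.compound_conc


@dataclass(frozen=True)
class StabilityResult:
    """Per-compound output of the buffer-stability screen."""

    compound_id: str
    lambda_star: float
    abs_diff: float
    rel_diff: float
    stability_class: str
    mechanism: str
    low_signal_flag: bool

    def __post_init__(self) -> None:
        if self.stability_class not in STABILITY_CLASSES:
            raise ContractError(f"bad class {self.stability_class!r}")
        if self.mechanism not in MECHANISMS:
            raise ContractError(f"bad mechanism {self.mechanism!r}")
        if self.rel_diff < 0:
            raise ContractError("rel_diff must be >= 0")
        if self.stability_class == "stable" and self.mechanism not in ("none",):
            raise ContractError("stable compounds carry mechanism 'none'")


@dataclass(frozen=True)
class ReactivityCall:
    """Reactivity of one compound-reagent pair against its blank."""

    compound_id: str
    reagent: str
    rel_diff_vs_blank: float
    reactive: bool
    hyperreactive: bool

    def __post_init__(self) -> None:
        if self.hyperreactive and not self.reactive:
            raise ContractError("hyperreactive implies reactive")


@dataclass(frozen=True)
class DecayFit:
    """One-phase exponential decay fit A(t) = plateau + (a0-plateau) e^(-k t).

    ``a0`` is the modeled absorbance at t=0 (mixing), extrapolated behind
    the instrument dead time.  ``fraction_complete_at_first_read`` is
    1 - e^(-k_obs * t_first) under the fitted model; above 0.95 the series
    is treated as hyperreactive and only ``k_obs_lower_bound`` is
    trustworthy.
    """

    a0: float
    plateau: float
    k_obs: float
    rms_residual: float
    converged: bool
    fraction_complete_at_first_read: float
    k_obs_lower_bound: Optional[float] = None

    @property
    def span(self) -> float:
        return self.a0 - self.plateau


@dataclass(frozen=True)
class K2Estimate:
    """Second-order rate constant with provenance of its estimation route."""

    k2: float
    method: str  # "single_conc" | "multi_conc_slope"
    n_points: int
    intercept: Optional[float] = None
    r_squared: Optional[float] = None

    def __post_init__(self) -> None:
        if self.method not in ("single_conc", "multi_conc_slope"):
            raise ContractError(f"unknown method {self.method!r}")
        if self.method == "single_conc":
            if self.n_points != 1 or self.intercept is not None \
                    or self.r_squared is not None:
                raise ContractError(
                    "single_conc estimates have n_points=1 and no regression "
                    "diagnostics")
        if self.k2 <= 0:
            raise ContractError("k2 must be positive")


@dataclass(frozen=True)
class CompoundRecord:
    """Scaffold annotation used by the global score."""

    compound_id: str
    core: str  # CBI | MeCBI | CBT | CBO
    substituent: str
    position: int

    CORES = ("CBI", "MeCBI", "CBT", "CBO")
    SUBSTITUENTS = ("NO2", "CO2Me", "CO2H", "Cl", "Me", "OMe", "OH", "NH2", "H")

    def __post_init__(self) -> None:
        if self.core not in self.CORES:
            raise ContractError(f"unknown core {self.core!r}")
        if self.substituent not in self.SUBSTITUENTS:
            raise ContractError(f"unknown substituent {self.substituent!r}")
        if self.position not in (4, 5, 6, 7):
            raise ContractError("position must be one of 4,5,6,7")

    @property
    def derivatizable(self) -> bool:
        """Amino, hydroxyl and carboxyl substituents offer attachment points."""
        return self.substituent in ("NH2", "OH", "CO2H")


@dataclass(frozen=True)
class GlobalScore:
    """Reactivity + selectivity + derivatization composite, each in [0, 1]."""

    compound_id: str
    reactivity_component: float
    selectivity_component: float
    derivatization_component: float
    total: float
    weights: tuple = (1.0, 1.0, 1.0)
    formula_id: str = "default-v1"

    def __post_init__(self) -> None:
        for name in ("reactivity_component", "selectivity_component"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ContractError(f"{name} out of [0,1]: {v}")
        if self.derivatization_component not in (0.0, 1.0):
            raise ContractError("derivatization_component must be 0 or 1")
        if any(w < 0 for w in self.weights):
            raise ContractError("weights must be nonnegative")


@dataclass
class PlateWell:
    """A spectral series paired with its layout condition."""

    series: SpectralTimeSeries
    condition: WellCondition


RESULT_TYPES = {
    "StabilityResult": StabilityResult,
    "ReactivityCall": ReactivityCall,
    "DecayFit": DecayFit,
    "K2Estimate": K2Estimate,
    "GlobalScore": GlobalScore,
}
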