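"""Synthetic plate and LCMS data with known ground truth.

Every downstream stage of the screen is validated by parameter recovery on
data from this module.  Spectra follow Beer-Lambert absorbance of
parent/product mixtures whose absorptivities are sums of Gaussian bands;
reaction progress is exponential (pseudo-first-order) or exact
second-order; degradation conserves total moles and therefore exhibits an
isosbestic point wherever the parent and product absorptivities are equal;
plate-wall binding scales the whole spectrum uniformly.  Measurement noise
is additive i.i.d. Gaussian per (time, wavelength) cell.  LCMS peak tables
carry species masses following the thiazoline/thioimidate adduct
arithmetic of :mod:`cbxscreen.masses`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, AssayConfig
from .errors import ContractError
from .kinetics import second_order_conversion
from .labeling import PeakRecord
from .masses import (
    AdductSpecies,
    MolecularFormula,
    disulfide_species,
    enumerate_adducts,
    parse_formula,
    peptide_formula,
)
from .types import SpectralTimeSeries

SCENARIOS = ("stable", "stable_drift", "isosbestic_degradation",
             "plate_binding", "pseudo_first_order", "second_order")

#: Model undecapeptides used throughout the labeling experiments:
#: UP1 carries the N-terminal cysteine, UP2 replaces it with alanine.
PEPTIDES: dict[str, tuple[str, bool]] = {
    "UP1": ("CGKGCGSGYGW", True),
    "UP2": ("AGKGCGSGYGW", False),
}

#: Default plate-reader noise floor, AU (per time x wavelength cell).
DEFAULT_NOISE_SD = 0.003


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian absorption band of a species' absorptivity spectrum.

    ``height`` is the absorbance at unit (molar) concentration at the band
    center, i.e. molar absorptivity x path length, pre-multiplied.
    """

    center: float  # nm
    width: float   # nm (standard deviation)
    height: float  # AU per molar

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ContractError("band width must be positive")
        if self.height < 0:
            raise ContractError("band height must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    """Hidden parameters of one simulated well; the recovery-test oracle.

    ``true_k`` is s^-1 for first-order scenarios and s^-1 M^-1 for
    ``second_order``.  ``c0`` is the compound concentration (molar);
    ``nucleophile_conc`` is required by ``second_order``.
    """

    scenario: str
    true_k: float
    parent_bands: tuple
    product_bands: tuple
    c0: float
    noise_sd: float
    seed: int
    nucleophile_conc: Optional[float] = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ContractError(f"unknown scenario {self.scenario!r}")
        if self.noise_sd < 0:
            raise ContractError("noise_sd must be nonnegative")
        if self.scenario == "second_order" and self.nucleophile_conc is None:
            raise ContractError(
                "second_order scenario needs both initial concentrations")
        if self.scenario != "stable" and self.true_k <= 0:
            raise ContractError("kinetic scenarios need true_k > 0")


def default_wavelengths() -> np.ndarray:
    """250-490 nm in 2 nm steps (121 points)."""
    return np.arange(250.0, 491.0, 2.0)


def default_timepoints(config: AssayConfig = DEFAULT_CONFIG,
                       n: int = 49) -> np.ndarray:
    """n reads evenly spaced from the dead time to the end of monitoring."""
    return np.linspace(config.dead_time, config.duration, n)


def gaussian_spectrum(bands: Iterable[GaussianBand],
                      wavelengths: Sequence[float]) -> np.ndarray:
    """Sum of Gaussian band profiles on a wavelength grid (AU per molar).

    An empty band list yields the zero spectrum.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size == 0:
        raise ContractError("wavelength grid must be nonempty")
    out = np.zeros_like(wl)
    for b in bands:
        out += b.height * np.exp(-0.5 * ((wl - b.center) / b.width) ** 2)
    return out


def _noise(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    return rng.normal(0.0, sd, size=shape)


def simulate_stability_scenario(truth: GroundTruth,
                                config: AssayConfig = DEFAULT_CONFIG,
                                wavelengths: Optional[np.ndarray] = None,
                                timepoints: Optional[np.ndarray] = None,
                                well_id: str = "A1",
                                compound_id: str = "cpd",
                                ) -> SpectralTimeSeries:
    """Simulate a buffer-stability well.

    ``stable``: constant spectrum plus noise.  ``isosbestic_degradation``:
    first-order parent -> product conversion conserving total moles,
    A(t, l) = c0 [e_p(l) e^(-kt) + e_q(l) (1 - e^(-kt))] + noise, so an
    exact isosbestic wavelength exists wherever e_p = e_q.
    ``plate_binding``: A(t, l) = c0 e_p(l) e^(-kt) + noise — every
    wavelength scales together and no crossing exists.
    """
    if truth.scenario not in ("stable", "isosbestic_degradation",
                              "plate_binding"):
        raise ContractError(
            f"{truth.scenario!r} is not a stability scenario")
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, float)
    tt = default_timepoints(config) if timepoints is None else np.asarray(timepoints, float)
    eps_p = gaussian_spectrum(truth.parent_bands, wl)
    decay = np.exp(-truth.true_k * tt)[:, None] if truth.scenario != "stable" else None
    if truth.scenario == "stable":
        grid = np.tile(truth.c0 * eps_p, (tt.size, 1))
    elif truth.scenario == "plate_binding":
        grid = truth.c0 * decay * eps_p[None, :]
    else:
        eps_q = gaussian_spectrum(truth.product_bands, wl)
        grid = truth.c0 * (decay * eps_p[None, :] + (1.0 - decay) * eps_q[None, :])
    rng = np.random.default_rng(truth.seed)
    grid = grid + _noise(rng, truth.noise_sd, grid.shape)
    return SpectralTimeSeries(well_id=well_id, compound_id=compound_id,
                              timepoints=tt, wavelengths=wl, absorbance=grid)


def isosbestic_band_pair(lambda_star: float = 340.0,
                         parent_center: float = 330.0,
                         product_center: float = 370.0,
                         width: float = 25.0,
                         parent_height: float = 1.0,
                         ) -> tuple[GaussianBand, GaussianBand]:
    """Construct equal-width parent/product bands crossing at ``lambda_star``.

    With equal widths the two Gaussians intersect at exactly one
    wavelength, giving a clean single isosbestic point; the product height
    is solved analytically so the crossing lands where requested (pick a
    grid wavelength for an exact zero-variance point in noiseless data).
    """
    g = lambda c: math.exp(-0.5 * ((lambda_star - c) / width) ** 2)
    product_height = parent_height * g(parent_center) / g(product_center)
    return (GaussianBand(parent_center, width, parent_height),
            GaussianBand(product_center, width, product_height))


def simulate_kinetics_series(true_k2: float,
                             compound_conc: float,
                             cys_concs: Sequence[float],
                             config: AssayConfig = DEFAULT_CONFIG,
                             seed: int = 0,
                             mode: str = "pseudo_first_order",
                             noise_sd: float = DEFAULT_NOISE_SD,
                             parent_bands: Optional[Sequence[GaussianBand]] = None,
                             product_bands: Optional[Sequence[GaussianBand]] = None,
                             wavelengths: Optional[np.ndarray] = None,
                             timepoints: Optional[np.ndarray] = None,
                             allow_low_excess: bool = False,
                             ) -> list[SpectralTimeSeries]:
    """Simulate compound + cysteine reaction wells, one per [Cys].

    In ``pseudo_first_order`` mode the parent decays as e^(-k_obs t) with
    k_obs = true_k2 x [Cys]; in ``second_order`` mode the exact progress
    law is used (cysteine depletes).  The product spectrum grows by mole
    conservation of the compound; noise is added last.  Concentrations
    below 10x excess are rejected unless ``allow_low_excess``.
    """
    cys_concs = list(cys_concs)
    if not cys_concs:
        raise ContractError("empty cysteine concentration list")
    if mode not in ("pseudo_first_order", "second_order"):
        raise ContractError(f"unknown kinetics mode {mode!r}")
    if not allow_low_excess:
        low = [c for c in cys_concs if c < 10.0 * compound_conc]
        if low:
            raise ContractError(
                f"cysteine concentrations {low} below 10x excess over the "
                "compound; pass allow_low_excess=True to simulate anyway")
    if parent_bands is None:
        parent_bands = (GaussianBand(348.0, 25.0, 12000.0),)
    if product_bands is None:
        product_bands = (GaussianBand(300.0, 25.0, 9000.0),)
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, float)
    tt = default_timepoints(config) if timepoints is None else np.asarray(timepoints, float)
    eps_p = gaussian_spectrum(parent_bands, wl)
    eps_q = gaussian_spectrum(product_bands, wl)
    rng = np.random.default_rng(seed)
    out = []
    for i, cys in enumerate(cys_concs):
        if mode == "pseudo_first_order":
            parent_frac = np.exp(-true_k2 * cys * tt)
        else:
            parent_frac = np.array([
                1.0 - second_order_conversion(true_k2, cys, compound_conc, t)
                for t in tt])
        b = compound_conc * parent_frac
        grid = b[:, None] * eps_p[None, :] + \
            (compound_conc - b)[:, None] * eps_q[None, :]
        grid = grid + _noise(rng, noise_sd, grid.shape)
        out.append(SpectralTimeSeries(
            well_id=f"K{i + 1}", compound_id="cpd", timepoints=tt,
            wavelengths=wl, absorbance=grid))
    return out


# ---------------------------------------------------------------------------
# stability suite: a labeled cohort spanning the three classes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuiteEntry:
    series: SpectralTimeSeries
    truth: GroundTruth
    true_class: str       # from the planted (noiseless) relative difference
    planted_rel_diff: float


def _rel_to_k(rel: float, t_first: float, t_last: float) -> float:
    """Decay rate whose uniform scaling yields the requested relative drop.

    For A(t) proportional to e^(-kt), the relative difference between the
    first and last read is 1 - e^(-k (t_last - t_first)).
    """
    return -math.log(1.0 - rel) / (t_last - t_first)


def _isosbestic_rate_for_rel(rel: float, eps_p: np.ndarray,
                             eps_q: np.ndarray, t_first: float,
                             t_last: float) -> float:
    """Rate giving the planted relative-difference statistic, analytically.

    For parent -> product conversion the change profile is proportional to
    (e_p - e_q), so the most responsive wavelength is k-independent; at
    that wavelength the relative difference between the first and last
    read is a monotone function of k (within the screen's time window),
    solved here by bisection.
    """
    from scipy.optimize import brentq

    j = int(np.argmax(np.abs(eps_p - eps_q)))

    def rel_of_k(k: float) -> float:
        d1, dn = math.exp(-k * t_first), math.exp(-k * t_last)
        num = (d1 - dn) * abs(eps_p[j] - eps_q[j])
        den = eps_p[j] * d1 + eps_q[j] * (1.0 - d1)
        return num / den

    return brentq(lambda k: rel_of_k(k) - rel, 1e-9, 5e-4, xtol=1e-12)


def simulate_stability_suite(n_series: int,
                             noise_sd: float = DEFAULT_NOISE_SD,
                             seed: int = 0,
                             config: AssayConfig = DEFAULT_CONFIG,
                             ) -> list[SuiteEntry]:
    """Generate a labeled stability cohort spanning the three classes.

    The planted quantity is the value the screen's statistic takes on
    noiseless data: the relative absorbance difference at the most
    responsive wavelength.  Classes keep margins from the 0.1/0.2
    decision boundaries (stable: [0.03, 0.07] — a small real drift;
    intermediate: [0.125, 0.175]; unstable: [0.25, 0.9] for plate binding
    and [0.25, 0.45] for degradation, whose two-chromophore geometry caps
    the achievable statistic) because boundary cases are undecidable at
    any finite noise by construction.  First-read peak absorbance is
    drawn from [0.3, 1.2] AU.  Non-stable series split evenly between
    isosbestic degradation (symmetric equal-height band pair whose
    crossing lands on the wavelength grid) and plate binding.
    """
    rng = np.random.default_rng(seed)
    tt = default_timepoints(config)
    wl = default_wavelengths()
    t_first, t_last = tt[0], tt[-1]
    entries: list[SuiteEntry] = []
    for i in range(n_series):
        cls = ("stable", "intermediate", "unstable")[i % 3]
        a0 = rng.uniform(0.3, 1.2)
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        mech_is_iso = bool(rng.integers(0, 2)) if cls != "stable" else False
        if cls == "stable":
            rel = rng.uniform(0.03, 0.07)
        elif cls == "intermediate":
            rel = rng.uniform(0.125, 0.175)
        elif mech_is_iso:
            rel = rng.uniform(0.25, 0.45)
        else:
            rel = rng.uniform(0.25, 0.9)

        if cls == "stable":
            # stable compounds still drift slightly (uniform scaling)
            k = _rel_to_k(rel, t_first, t_last)
            bands = (GaussianBand(float(rng.uniform(300, 420)), 25.0, a0),)
            truth = GroundTruth("stable_drift", k, bands, (), c0=1.0,
                                noise_sd=noise_sd, seed=sub_seed)
        elif mech_is_iso:
            # shorter product band, crossing planted on the 2 nm grid; the
            # asymmetry keeps the most responsive wavelength on the
            # parent's high-baseline side
            c_p = float(rng.choice(np.arange(310.0, 401.0, 2.0)))
            p_band, q_band = isosbestic_band_pair(
                lambda_star=c_p + 20.0, parent_center=c_p,
                product_center=c_p + 30.0, width=25.0, parent_height=a0)
            eps_p = gaussian_spectrum((p_band,), wl)
            eps_q = gaussian_spectrum((q_band,), wl)
            k = _isosbestic_rate_for_rel(rel, eps_p, eps_q, t_first, t_last)
            truth = GroundTruth("isosbestic_degradation", k, (p_band,),
                                (q_band,), c0=1.0, noise_sd=noise_sd,
                                seed=sub_seed)
        else:
            k = _rel_to_k(rel, t_first, t_last)
            bands = (GaussianBand(float(rng.uniform(300, 420)), 25.0, a0),)
            truth = GroundTruth("plate_binding", k, bands, (), c0=1.0,
                                noise_sd=noise_sd, seed=sub_seed)
        scenario_truth = truth if truth.scenario != "stable_drift" else \
            GroundTruth("plate_binding", truth.true_k, truth.parent_bands,
                        (), c0=1.0, noise_sd=noise_sd, seed=sub_seed)
        series = simulate_stability_scenario(
            scenario_truth, config, wavelengths=wl, timepoints=tt,
            well_id=f"S{i + 1}", compound_id=f"cpd{i + 1}")
        entries.append(SuiteEntry(series=series, truth=truth, true_class=cls,
                                  planted_rel_diff=rel))
    return entries


# ---------------------------------------------------------------------------
# LCMS labeling experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelingTruth:
    """Ground truth of one simulated labeling run."""

    peptide_id: str
    compound_id: str
    k2: float
    conversion_pct: float
    species_by_peak: tuple  # of (peak_id, (n_labels, n_thiazoline))


#: k2 (s^-1 M^-1) above which simulated runs show di- (and, 10x higher,
#: tri-) labeled adducts, mirroring multi-labeling by the most reactive
#: electrophiles.  5 s^-1 M^-1 is the complete-labeling threshold.
MULTILABEL_K2 = 5.0
TRILABEL_K2 = 50.0

_BLANK_AREA = 1000.0


def simulate_labeling_experiment(k2_by_compound: dict[str, float],
                                 peptide: str,
                                 compound_formulas: dict[str, str],
                                 equivalents: float = 2.0,
                                 duration: float = 1800.0,
                                 seed: int = 0,
                                 peptide_conc: float = 2.5e-5,
                                 config: AssayConfig = DEFAULT_CONFIG,
                                 area_noise_rel: float = 0.0,
                                 include_disulfide: bool = False,
                                 ) -> dict[str, tuple[list[PeakRecord], LabelingTruth]]:
    """Simulate LCMS peak tables for compounds incubated with a peptide.

    Conversion of the peptide comes from the exact second-order law with
    the compound at ``equivalents`` x ``peptide_conc``.  Emitted peaks:
    residual parent peptide (area proportional to 1 - conversion), the
    monoadduct (thiazoline for an N-terminal-cysteine peptide, thioimidate
    otherwise), and reversible di/tri adducts for compounds above
    ``MULTILABEL_K2`` / ``TRILABEL_K2``.  Observed m/z values are the
    theoretical ones perturbed by uniform mass noise within
    +- ppm_tolerance/2.
    """
    if equivalents <= 0:
        raise ContractError("equivalents must be positive")
    if peptide not in PEPTIDES:
        raise ContractError(f"unknown peptide label {peptide!r}")
    seq, has_ncys = PEPTIDES[peptide]
    pep_formula = peptide_formula(seq)
    rng = np.random.default_rng(seed)
    half_tol = config.ppm_tolerance / 2.0
    out: dict[str, tuple[list[PeakRecord], LabelingTruth]] = {}
    for cpd_id, k2 in k2_by_compound.items():
        cpd_formula = parse_formula(compound_formulas[cpd_id])
        a0 = equivalents * peptide_conc
        conv = 0.0 if k2 == 0 else second_order_conversion(
            k2, a0, peptide_conc, duration)
        if conv > 1.0 - 1e-9:
            conv = 1.0
        species = enumerate_adducts(pep_formula, has_ncys, cpd_formula,
                                    max_labels=3, peptide_id=peptide,
                                    compound_id=cpd_id)
        by_key = {(s.n_labels, s.n_thiazoline): s for s in species}

        peaks: list[PeakRecord] = []
        truth_pairs: list[tuple[str, tuple[int, int]]] = []
        rt = 4.0

        def emit(key: tuple[int, int], area: float) -> None:
            nonlocal rt
            s = by_key[key]
            if area_noise_rel > 0:
                area *= 1.0 + rng.normal(0.0, area_noise_rel)
                area = max(area, 0.0)
            ppm_shift = rng.uniform(-half_tol, half_tol)
            mz = s.theoretical_mz * (1.0 + ppm_shift * 1e-6)
            pid = f"{cpd_id}_p{len(peaks) + 1}"
            peaks.append(PeakRecord(peak_id=pid, retention_time=rt,
                                    area_280=area, observed_mzs=(mz,)))
            truth_pairs.append((pid, key))
            rt += 0.8

        parent_area = _BLANK_AREA * (1.0 - conv)
        if parent_area > 1e-9:
            emit((0, 0), parent_area)
        if conv > 0:
            mono_key = (1, 1) if has_ncys else (1, 0)
            n_adduct_kinds = 1 + (k2 > MULTILABEL_K2) + \
                (k2 > TRILABEL_K2 and has_ncys)
            share = _BLANK_AREA * conv / n_adduct_kinds
            emit(mono_key, share)
            if k2 > MULTILABEL_K2:
                emit((2, 1) if has_ncys else (2, 0), share)
            if k2 > TRILABEL_K2 and has_ncys:
                emit((3, 1), share)
        if include_disulfide:
            ds = disulfide_species(pep_formula, peptide_id=peptide)
            ppm_shift = rng.uniform(-half_tol, half_tol)
            mz = ds.theoretical_mz * (1.0 + ppm_shift * 1e-6)
            peaks.append(PeakRecord(peak_id=f"{cpd_id}_ds",
                                    retention_time=rt, area_280=20.0,
                                    observed_mzs=(mz,)))
            truth_pairs.append((f"{cpd_id}_ds", (-1, -1)))  # sentinel
        out[cpd_id] = (peaks, LabelingTruth(
            peptide_id=peptide, compound_id=cpd_id, k2=k2,
            conversion_pct=100.0 * conv,
            species_by_peak=tuple(truth_pairs)))
    return out


def simulate_treatment(peaks: Sequence[PeakRecord], truth: LabelingTruth,
                       treatment: str, compound_formula: str,
                       ) -> tuple[list[PeakRecord], LabelingTruth]:
    """Simulate post-labeling Cys or DTT treatment of a peak table.

    Free cysteine scavenges the reversible thioimidate labels: every such
    label is stripped, the species collapses onto its thiazoline-only or
    parent counterpart, and peak areas merge.  DTT leaves the table
    unchanged.  The treated table is re-"measured" with exact theoretical
    m/z values.
    """
    if treatment not in ("Cys", "DTT"):
        raise ContractError("treatment must be 'Cys' or 'DTT'")
    if treatment == "DTT":
        return list(peaks), truth
    seq, has_ncys = PEPTIDES[truth.peptide_id]
    pep_formula = peptide_formula(seq)
    cpd = parse_formula(compound_formula)
    species = enumerate_adducts(pep_formula, has_ncys, cpd, max_labels=3,
                                peptide_id=truth.peptide_id,
                                compound_id=truth.compound_id)
    by_key = {(s.n_labels, s.n_thiazoline): s for s in species}
    key_by_peak = dict(truth.species_by_peak)
    # strip thioimidate labels -> merge areas by surviving species key
    merged: dict[tuple[int, int], float] = {}
    for p in peaks:
        key = key_by_peak.get(p.peak_id)
        if key is None or key == (-1, -1):
            key = (-1, -1)  # disulfide / unassigned: carried through
        else:
            key = (key[1], key[1])  # only the thiazoline label survives
        merged[key] = merged.get(key, 0.0) + p.area_280
    new_peaks: list[PeakRecord] = []
    new_pairs: list[tuple[str, tuple[int, int]]] = []
    rt = 4.0
    for key in sorted(merged):
        if merged[key] <= 1e-9:
            continue
        if key == (-1, -1):
            ds = disulfide_species(pep_formula, peptide_id=truth.peptide_id)
            mz = ds.theoretical_mz
        else:
            mz = by_key[key].theoretical_mz
        pid = f"{truth.compound_id}_t{len(new_peaks) + 1}"
        new_peaks.append(PeakRecord(peak_id=pid, retention_time=rt,
                                    area_280=merged[key], observed_mzs=(mz,)))
        new_pairs.append((pid, key))
        rt += 0.8
    new_truth = replace(truth, species_by_peak=tuple(new_pairs))
    return new_peaks, new_truth
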