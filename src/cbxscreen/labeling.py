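"""LCMS interpretation of oligopeptide-labeling experiments.

Conversion is semiquantified from parent-peptide depletion: the 280 nm
peak area of the parent peptide after incubation is compared with the
untreated blank.  Product peaks are assigned to enumerated adduct species
by accurate mass; the NH3-loss rule separates the irreversible N-terminal
thiazoline from reversible additions.  A follow-up cysteine treatment
strips reversible thioimidate labels (free cysteine both scavenges the
excess nitrile and displaces the open adduct), while dithiothreitol — a
thiol without the 1,2-aminothiol motif — should change nothing.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .config import DEFAULT_CONFIG, AssayConfig
from .errors import ContractError, PlateFormatError
from .masses import AdductSpecies, match_peak

AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class PeakRecord:
    """One integrated LCMS peak: retention time, 280 nm area, m/z list."""

    peak_id: str
    retention_time: float  # minutes
    area_280: float        # AU*s
    observed_mzs: tuple

    def __post_init__(self) -> None:
        if self.area_280 < 0:
            raise ContractError("peak area must be >= 0")
        if self.retention_time <= 0:
            raise ContractError("retention time must be positive")


@dataclass(frozen=True)
class Conversion:
    percent: float
    clamped_negative: bool = False


@dataclass
class LabelingResult:
    """Outcome of one peptide + compound labeling run."""

    peptide_id: str
    compound_id: str
    conversion_pct: float
    species_assignments: dict  # peak_id -> AdductSpecies | None | "ambiguous"
    complete_conversion: bool
    multi_labeling: bool
    reversible_present: bool
    negative_conversion_clamped: bool = False

    def assigned_species(self) -> list[AdductSpecies]:
        return [s for s in self.species_assignments.values()
                if isinstance(s, AdductSpecies)]


def conversion_from_auc(area_parent_treated: float,
                        area_parent_blank: float) -> Conversion:
    """Percent conversion from parent-peak depletion at 280 nm.

    100 x (1 - treated/blank), clamped to [0, 100]; a raw value below
    zero (treated area above the blank, e.g. injection variability) is
    clamped to 0 and flagged.
    """
    if area_parent_blank <= 0:
        raise ContractError("blank parent area must be positive")
    if area_parent_treated < 0:
        raise ContractError("areas must be >= 0")
    raw = 100.0 * (1.0 - area_parent_treated / area_parent_blank)
    if raw < 0:
        return Conversion(0.0, clamped_negative=True)
    return Conversion(min(raw, 100.0))


def assign_peaks(peaks: Sequence[PeakRecord],
                 candidates: Sequence[AdductSpecies],
                 blank_area: float,
                 config: AssayConfig = DEFAULT_CONFIG,
                 peptide_id: Optional[str] = None,
                 compound_id: Optional[str] = None) -> LabelingResult:
    """Assign every peak to an adduct species and quantify conversion.

    ``candidates`` must include the parent peptide (zero labels); the
    parent's area — zero when no peak matches it — against ``blank_area``
    gives the conversion.  Disulfide peaks are matched but excluded from
    the conversion arithmetic.
    """
    peaks = list(peaks)
    if not peaks:
        raise ContractError("empty peak list")
    if blank_area is None or blank_area <= 0:
        raise ContractError("a positive blank parent area is required")
    cands = list(candidates)
    if not any(c.is_parent for c in cands):
        raise ContractError("candidate list must include the parent peptide")

    assignments: dict = {}
    parent_area = 0.0
    multi = False
    reversible = False
    for peak in peaks:
        matches = match_peak(peak.observed_mzs, cands, config.ppm_tolerance)
        best: Union[AdductSpecies, None, str] = None
        for m in matches:
            if m.ambiguous:
                best = AMBIGUOUS
                break
            if m.species is not None:
                best = m.species
                break
        assignments[peak.peak_id] = best
        if isinstance(best, AdductSpecies):
            if best.is_parent:
                parent_area += peak.area_280
            if best.n_labels >= 2:
                multi = True
            if best.reversible:
                reversible = True
    conv = conversion_from_auc(parent_area, blank_area)
    complete = parent_area == 0.0
    pct = 100.0 if complete else conv.percent
    return LabelingResult(
        peptide_id=peptide_id or cands[0].peptide_id,
        compound_id=compound_id or next(
            (c.compound_id for c in cands if c.compound_id), "cpd"),
        conversion_pct=pct, species_assignments=assignments,
        complete_conversion=complete, multi_labeling=multi,
        reversible_present=reversible,
        negative_conversion_clamped=conv.clamped_negative)


@dataclass(frozen=True)
class ReversibilityReport:
    """Species bookkeeping across a Cys or DTT treatment."""

    peptide_id: str
    compound_id: str
    treatment: str
    reversible_species: tuple  # present before, absent after
    persistent_species: tuple  # present in both
    new_species: tuple         # absent before
    anomalies: tuple           # human-readable flags


def _species_keys(result: LabelingResult) -> set:
    keys = set()
    for s in result.assigned_species():
        if s.is_disulfide:
            continue
        keys.add((s.n_labels, s.n_thiazoline, s.n_thioimidate))
    return keys


def reversibility_check(before: LabelingResult, after: LabelingResult,
                        treatment: str) -> ReversibilityReport:
    """Classify species as reversible / persistent / new across a treatment.

    After a cysteine treatment any surviving thioimidate species is
    anomalous (the open adduct should hydrolyze or transfer to free Cys);
    after a DTT treatment any change at all is anomalous.
    """
    if treatment not in ("Cys", "DTT"):
        raise ContractError("treatment must be 'Cys' or 'DTT'")
    if (before.peptide_id, before.compound_id) != \
            (after.peptide_id, after.compound_id):
        raise ContractError("before/after results describe different runs")
    keys_before = _species_keys(before)
    keys_after = _species_keys(after)
    gone = tuple(sorted(keys_before - keys_after))
    kept = tuple(sorted(keys_before & keys_after))
    new = tuple(sorted(keys_after - keys_before))
    anomalies = []
    if treatment == "Cys":
        survivors = [k for k in keys_after if k[2] > 0]
        if survivors:
            anomalies.append(
                f"thioimidate species persisted through Cys treatment: "
                f"{sorted(survivors)}")
    else:
        if gone or new:
            anomalies.append(
                "species set changed under DTT treatment "
                f"(vanished {list(gone)}, appeared {list(new)})")
    return ReversibilityReport(
        peptide_id=before.peptide_id, compound_id=before.compound_id,
        treatment=treatment, reversible_species=gone,
        persistent_species=kept, new_species=new,
        anomalies=tuple(anomalies))


def read_peak_table(path: str | Path) -> list[PeakRecord]:
    """Read a peak-table CSV: peak_id,rt_min,area_280,mz_list.

    ``mz_list`` holds semicolon-separated m/z values.
    """
    path = Path(path)
    records = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"peak_id", "rt_min", "area_280", "mz_list"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or ()))
            raise PlateFormatError(f"peak table is missing column(s) {missing}")
        for row in reader:
            mzs = tuple(float(x) for x in row["mz_list"].split(";") if x)
            records.append(PeakRecord(
                peak_id=row["peak_id"], retention_time=float(row["rt_min"]),
                area_280=float(row["area_280"]), observed_mzs=mzs))
    return records


def write_peak_table(peaks: Sequence[PeakRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["peak_id", "rt_min", "area_280", "mz_list"])
        for p in peaks:
            writer.writerow([p.peak_id, repr(p.retention_time),
                             repr(p.area_280),
                             ";".join(repr(m) for m in p.observed_mzs)])


def labeling_result_to_json(result: LabelingResult, path: str | Path) -> None:
    payload = {
        "peptide_id": result.peptide_id,
        "compound_id": result.compound_id,
        "conversion_pct": result.conversion_pct,
        "complete_conversion": result.complete_conversion,
        "multi_labeling": result.multi_labeling,
        "reversible_present": result.reversible_present,
        "negative_conversion_clamped": result.negative_conversion_clamped,
        "species_assignments": {
            pid: (s if isinstance(s, str) or s is None else s.name)
            for pid, s in result.species_assignments.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
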