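"""Molecular-formula arithmetic, monoisotopic masses, and adduct enumeration.

The chemistry encoded here is the mass bookkeeping of nitrile-cysteine
bioconjugation: an N-terminal cysteine condenses with a heteroaromatic
nitrile to a thiazoline ring, eliminating one NH3 (17.0265 Da), while an
internal cysteine adds reversibly to the nitrile as a thioimidate with no
mass loss.  A peptide carrying both can therefore show adduct series whose
members differ by exactly one ammonia — the discriminator used to assign
labeling sites from high-resolution m/z alone.

Monoisotopic element masses come from the NIST table shipped with
pyteomics; formula parsing and the adduct arithmetic are implemented here.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from pyteomics import mass as _pmass

from .errors import ContractError, FormulaParseError

#: Principal-isotope masses (Da). Seeded from pyteomics' NIST table for the
#: elements of peptide/compound chemistry; extend in place for exotic atoms.
ELEMENT_MASSES: dict[str, float] = {
    el: _pmass.nist_mass[el][0][0] for el in ("C", "H", "N", "O", "P", "S")
}

#: Proton mass with the electron correction, for [M + zH]^z+ charging.
PROTON_MASS = 1.00727646677

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map restricted to the known element table."""

    counts: tuple  # sorted tuple of (element, count); hashable

    def __post_init__(self) -> None:
        for el, n in self.counts:
            if el not in ELEMENT_MASSES:
                raise ContractError(f"unknown element {el!r}")
            if not isinstance(n, int) or n <= 0:
                raise ContractError(f"count for {el} must be a positive int")

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "MolecularFormula":
        filtered = {el: int(n) for el, n in counts.items() if n != 0}
        if any(n < 0 for n in filtered.values()):
            raise ContractError("negative element count")
        return cls(tuple(sorted(filtered.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        c = Counter(self.as_dict())
        c.update(other.as_dict())
        return MolecularFormula.from_counts(dict(c))

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        c = Counter(self.as_dict())
        c.subtract(other.as_dict())
        if any(v < 0 for v in c.values()):
            raise ContractError("subtraction yields a negative element count")
        return MolecularFormula.from_counts({k: v for k, v in c.items() if v})

    def __mul__(self, n: int) -> "MolecularFormula":
        if not isinstance(n, int) or n < 0:
            raise ContractError("formula multiplier must be a nonnegative int")
        return MolecularFormula.from_counts(
            {el: c * n for el, c in self.counts})

    __rmul__ = __mul__


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string ("C3H7NO2S", implicit count 1).

    Unknown element symbols or malformed tokens raise
    :class:`FormulaParseError` carrying the character offset.
    """
    if not text or not text.strip():
        raise ContractError("empty formula string")
    text = text.strip()
    counts: Counter = Counter()
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaParseError(f"malformed token in {text!r}", pos)
        el, num = m.group(1), m.group(2)
        if el not in ELEMENT_MASSES:
            raise FormulaParseError(f"unknown element {el!r}", pos)
        counts[el] += int(num) if num else 1
        pos = m.end()
    return MolecularFormula.from_counts(dict(counts))


def format_formula(formula: MolecularFormula) -> str:
    """Hill order: C, H, then the rest alphabetically."""
    d = formula.as_dict()
    parts = []
    for el in ("C", "H"):
        if el in d:
            n = d.pop(el)
            parts.append(el + (str(n) if n > 1 else ""))
    for el in sorted(d):
        n = d[el]
        parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Sum of principal-isotope masses, in Da."""
    return sum(ELEMENT_MASSES[el] * n for el, n in formula.counts)


NH3 = parse_formula("NH3")
H2O = parse_formula("H2O")
H2 = parse_formula("H2")

NH3_MASS = monoisotopic_mass(NH3)


def peptide_formula(sequence: str) -> MolecularFormula:
    """Molecular formula of a linear peptide with free termini.

    Residue compositions come from pyteomics' standard amino-acid table;
    the sum gains one H2O for the termini.
    """
    if not sequence:
        raise ContractError("empty peptide sequence")
    counts: Counter = Counter()
    for i, aa in enumerate(sequence):
        comp = _pmass.std_aa_comp.get(aa)
        if comp is None:
            raise ContractError(
                f"unknown amino acid {aa!r} at position {i} in {sequence!r}")
        counts.update(comp)
    counts.update(_pmass.std_aa_comp["H-"])   # N-terminal H
    counts.update(_pmass.std_aa_comp["-OH"])  # C-terminal OH
    return MolecularFormula.from_counts(dict(counts))


def mz_of(mass_da: float, charge: int) -> float:
    """m/z of [M + zH]^z+ using the electron-corrected proton mass."""
    if not isinstance(charge, int) or charge < 1:
        raise ContractError("charge must be a positive integer")
    if mass_da <= 0:
        raise ContractError("mass must be positive")
    return (mass_da + charge * PROTON_MASS) / charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error in ppm; negative when observed < theoretical."""
    if theoretical <= 0:
        raise ContractError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class AdductSpecies:
    """An enumerated peptide-compound adduct with its theoretical m/z.

    ``n_labels = n_thiazoline + n_thioimidate``; the thiazoline count is
    capped at 1 (one N-terminus per peptide).  ``reversible`` marks species
    carrying any thioimidate label.  ``is_disulfide`` marks the built-in
    peptide-disulfide candidate (2 x peptide - 2 H), which is not a
    compound adduct at all.
    """

    peptide_id: str
    compound_id: Optional[str]
    n_labels: int
    n_thiazoline: int
    n_thioimidate: int
    charge: int
    theoretical_mz: float
    is_disulfide: bool = False

    def __post_init__(self) -> None:
        if self.n_thiazoline not in (0, 1):
            raise ContractError("at most one thiazoline per peptide")
        if self.n_labels != self.n_thiazoline + self.n_thioimidate:
            raise ContractError("n_labels must equal thiazoline + thioimidate")
        if self.theoretical_mz <= 0:
            raise ContractError("theoretical m/z must be positive")

    @property
    def reversible(self) -> bool:
        return self.n_thioimidate > 0

    @property
    def is_parent(self) -> bool:
        return self.n_labels == 0 and not self.is_disulfide

    @property
    def name(self) -> str:
        if self.is_disulfide:
            return f"({self.peptide_id})2-disulfide"
        if self.n_labels == 0:
            return self.peptide_id
        tag = f"{self.peptide_id}+{self.n_labels}x{self.compound_id}"
        if self.n_thiazoline:
            tag += "-NH3"
        return tag


def enumerate_adducts(peptide: MolecularFormula,
                      has_n_terminal_cys: bool,
                      compound: MolecularFormula,
                      max_labels: int,
                      charge: int = 1,
                      peptide_id: str = "peptide",
                      compound_id: str = "cpd") -> list[AdductSpecies]:
    """Enumerate all peptide-compound adducts up to ``max_labels``.

    For each label count n = 0..max_labels the species are: all labels as
    reversible thioimidate additions (mass = peptide + n x compound) and,
    when the peptide offers an N-terminal cysteine, the variant in which
    one label is the cyclized thiazoline (mass additionally down by one
    NH3).  Internal thioimidate cannot be distinguished by mass from other
    reversible additions (Ser/Tyr), so no site assignment is implied.
    """
    if max_labels < 1:
        raise ContractError("max_labels must be >= 1")
    pep_mass = monoisotopic_mass(peptide)
    cpd_mass = monoisotopic_mass(compound)
    species: list[AdductSpecies] = []
    for n in range(0, max_labels + 1):
        thiazoline_options = (0,) if (n == 0 or not has_n_terminal_cys) else (0, 1)
        for thia in thiazoline_options:
            m = pep_mass + n * cpd_mass - thia * NH3_MASS
            species.append(AdductSpecies(
                peptide_id=peptide_id, compound_id=compound_id if n else None,
                n_labels=n, n_thiazoline=thia, n_thioimidate=n - thia,
                charge=charge, theoretical_mz=mz_of(m, charge)))
    return species


def disulfide_species(peptide: MolecularFormula, charge: int = 1,
                      peptide_id: str = "peptide") -> AdductSpecies:
    """The intermolecular peptide disulfide (2 x peptide - 2 H) candidate."""
    m = 2 * monoisotopic_mass(peptide) - monoisotopic_mass(H2)
    return AdductSpecies(
        peptide_id=peptide_id, compound_id=None, n_labels=0, n_thiazoline=0,
        n_thioimidate=0, charge=charge, theoretical_mz=mz_of(m, charge),
        is_disulfide=True)


@dataclass(frozen=True)
class PeakAssignment:
    """Best candidate for one observed m/z, or none / ambiguous."""

    observed_mz: float
    species: Optional[AdductSpecies]
    ppm: Optional[float]
    ambiguous: bool = False
    ambiguous_candidates: tuple = ()


def match_peak(observed_mzs: Sequence[float],
               candidates: Iterable[AdductSpecies],
               tol: float) -> list[PeakAssignment]:
    """Assign each observed m/z to the candidate minimizing |ppm error|.

    An m/z with no candidate within ``tol`` ppm stays unassigned.  Two
    candidates both within tolerance and within 0.1 ppm of each other are
    reported as ambiguous rather than silently resolved.
    """
    if tol <= 0:
        raise ContractError("ppm tolerance must be positive")
    cands = list(candidates)
    out: list[PeakAssignment] = []
    for mz in observed_mzs:
        scored = sorted(
            ((abs(ppm_error(mz, c.theoretical_mz)), c) for c in cands),
            key=lambda sc: sc[0])
        within = [(e, c) for e, c in scored if e <= tol]
        if not within:
            out.append(PeakAssignment(mz, None, None))
            continue
        best_err, best = within[0]
        rivals = tuple(c for e, c in within[1:] if e - best_err <= 0.1)
        if rivals:
            out.append(PeakAssignment(mz, None, None, ambiguous=True,
                                      ambiguous_candidates=(best,) + rivals))
        else:
            out.append(PeakAssignment(
                mz, best, ppm_error(mz, best.theoretical_mz)))
    return out
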