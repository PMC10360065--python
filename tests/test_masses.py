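"""Formula parsing, monoisotopic masses, adduct enumeration, ppm matching."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cbxscreen.errors import ContractError, FormulaParseError
from cbxscreen.masses import (
    NH3_MASS,
    disulfide_species,
    enumerate_adducts,
    format_formula,
    match_peak,
    monoisotopic_mass,
    mz_of,
    parse_formula,
    peptide_formula,
    ppm_error,
)

# independent residue-mass oracle: published monoisotopic residue masses
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "C": 103.00919,
    "K": 128.09496, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.010565


class TestParseFormula:
    def test_simple_parses(self):
        assert parse_formula("NH3").as_dict() == {"N": 1, "H": 3}
        assert parse_formula("C3H7NO2S").as_dict() == \
            {"C": 3, "H": 7, "N": 1, "O": 2, "S": 1}

    def test_unknown_element_with_offset(self):
        with pytest.raises(FormulaParseError) as exc:
            parse_formula("C2Xx2")
        assert exc.value.offset == 2

    def test_order_insensitive(self):
        assert parse_formula("H3N") == parse_formula("NH3")

    @given(counts=st.dictionaries(
        st.sampled_from(["C", "H", "N", "O", "P", "S"]),
        st.integers(1, 40), min_size=1, max_size=6))
    def test_parse_format_round_trip(self, counts):
        from cbxscreen.masses import MolecularFormula
        f = MolecularFormula.from_counts(counts)
        assert parse_formula(format_formula(f)) == f


class TestMonoisotopicMass:
    def test_ammonia_discriminator_mass(self):
        assert monoisotopic_mass(parse_formula("NH3")) == \
            pytest.approx(17.0265, abs=5e-5)

    def test_water(self):
        assert monoisotopic_mass(parse_formula("H2O")) == \
            pytest.approx(18.0106, abs=5e-5)

    @given(a=st.dictionaries(st.sampled_from(["C", "H", "N", "O", "S"]),
                             st.integers(1, 30), min_size=1, max_size=4),
           b=st.dictionaries(st.sampled_from(["C", "H", "N", "O", "S"]),
                             st.integers(1, 30), min_size=1, max_size=4))
    def test_additivity(self, a, b):
        from cbxscreen.masses import MolecularFormula
        fa = MolecularFormula.from_counts(a)
        fb = MolecularFormula.from_counts(b)
        assert monoisotopic_mass(fa) + monoisotopic_mass(fb) == \
            pytest.approx(monoisotopic_mass(fa + fb), abs=1e-9)


class TestPeptideFormula:
    def test_glycine(self):
        f = peptide_formula("G")
        assert f == parse_formula("C2H5NO2")
        assert monoisotopic_mass(f) == pytest.approx(75.0320, abs=5e-5)

    def test_condensation_identity(self):
        gg = monoisotopic_mass(peptide_formula("GG"))
        g = monoisotopic_mass(peptide_formula("G"))
        water = monoisotopic_mass(parse_formula("H2O"))
        assert gg == pytest.approx(2 * g - water, abs=1e-9)

    @pytest.mark.parametrize("seq", ["CGKGCGSGYGW", "AGKGCGSGYGW"])
    def test_undecapeptides_against_residue_table_oracle(self, seq):
        expected = sum(RESIDUE_MASS[a] for a in seq) + WATER
        assert monoisotopic_mass(peptide_formula(seq)) == \
            pytest.approx(expected, abs=2e-4)

    def test_unknown_letter_rejected(self):
        with pytest.raises(ContractError):
            peptide_formula("GXZ")


class TestMzAndPpm:
    def test_proton_addition(self):
        assert mz_of(121.0197, 1) == pytest.approx(122.0270, abs=5e-4)
        m = 500.0
        assert mz_of(m, 2) == pytest.approx((m + 2 * 1.00727646677) / 2)

    def test_charge_guard(self):
        with pytest.raises(ContractError):
            mz_of(100.0, 0)

    def test_ppm_arithmetic_and_sign(self):
        assert ppm_error(500.0005, 500.0) == pytest.approx(1.0)
        assert ppm_error(440.0676, 440.0676) == 0.0
        assert ppm_error(440.0672, 440.0676) < 0  # observed low -> negative

    def test_ppm_guard(self):
        with pytest.raises(ContractError):
            ppm_error(100.0, 0.0)


CBT_CORE = "C8H4N2S"  # 2-cyanobenzothiazole


class TestEnumerateAdducts:
    def _species(self, has_cys, max_labels=3):
        pep = peptide_formula("CGKGCGSGYGW" if has_cys else "AGKGCGSGYGW")
        return enumerate_adducts(pep, has_cys, parse_formula(CBT_CORE),
                                 max_labels)

    def test_no_nh3_loss_without_n_terminal_cys(self):
        species = self._species(has_cys=False, max_labels=2)
        assert all(s.n_thiazoline == 0 for s in species)
        # parent, mono, di
        assert sorted(s.n_labels for s in species) == [0, 1, 2]

    def test_monoadduct_pair_differs_by_ammonia(self):
        species = self._species(has_cys=True)
        monos = [s for s in species if s.n_labels == 1]
        assert len(monos) == 2
        thio = next(s for s in monos if s.n_thioimidate == 1)
        thia = next(s for s in monos if s.n_thiazoline == 1)
        assert thio.theoretical_mz - thia.theoretical_mz == \
            pytest.approx(NH3_MASS, abs=1e-5)
        assert thio.reversible and not thia.reversible

    def test_trilabeled_species_present(self):
        species = self._species(has_cys=True, max_labels=3)
        assert any(s.n_labels == 3 for s in species)

    def test_ammonia_gap_invariant_across_compounds(self):
        """Thioimidate vs thiazoline monoadduct differ by one NH3 always."""
        pep = peptide_formula("CGKGCGSGYGW")
        for formula in ("C8H4N2S", "C8H4N2O", "C9H7N3", "C9H4N2O2S2"):
            sp = enumerate_adducts(pep, True, parse_formula(formula), 1)
            monos = {s.n_thioimidate: s for s in sp if s.n_labels == 1}
            gap = monos[1].theoretical_mz - monos[0].theoretical_mz
            assert gap == pytest.approx(17.02655, abs=1e-5)


class TestMatchPeak:
    def _cands(self):
        pep = peptide_formula("CGKGCGSGYGW")
        return enumerate_adducts(pep, True, parse_formula(CBT_CORE), 2)

    def test_exact_match_zero_ppm(self):
        cands = self._cands()
        target = cands[1]
        [a] = match_peak([target.theoretical_mz], cands, tol=5.0)
        assert a.species == target
        assert a.ppm == pytest.approx(0.0, abs=1e-9)

    def test_out_of_tolerance_unassigned(self):
        cands = self._cands()[:1]
        mz = cands[0].theoretical_mz * (1 + 10e-6)  # 10 ppm off
        [a] = match_peak([mz], cands, tol=5.0)
        assert a.species is None and not a.ambiguous

    def test_near_degenerate_candidates_reported_ambiguous(self):
        cands = self._cands()
        c = cands[0]
        import dataclasses
        twin = dataclasses.replace(
            c, theoretical_mz=c.theoretical_mz * (1 + 0.05e-6))
        [a] = match_peak([c.theoretical_mz], [c, twin], tol=5.0)
        assert a.ambiguous and a.species is None
        assert len(a.ambiguous_candidates) == 2

    def test_disulfide_candidate_mass(self):
        pep = peptide_formula("CGKGCGSGYGW")
        ds = disulfide_species(pep)
        expected = 2 * monoisotopic_mass(pep) - 2 * 1.00782503207
        assert ds.theoretical_mz == pytest.approx(
            expected + 1.00727646677, abs=1e-5)
        assert ds.is_disulfide and not ds.is_parent
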