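"""Formula arithmetic, monoisotopic masses, adduct m/z and naming."""

import pytest
from hypothesis import given
from hypothesis import strategies as st
from pyteomics import mass as pyteomics_mass

from loxotype import chem
from loxotype.chem import (
    EPA,
    Derivatization,
    ElementalFormula,
    FattyAcid,
    OxylipinClass,
    OxylipinSpecies,
    adduct_mz,
    canonical_name,
    formula_of,
    monoisotopic_mass,
    parse_name,
)
from loxotype.errors import UnsupportedSpeciesError, ValidationError

ME = Derivatization.METHYL_ESTER


class TestFormulas:
    @pytest.mark.parametrize("species,deriv,expected", [
        (chem.hepe(15), Derivatization.NONE, "C20H30O3"),
        (chem.hepe(15), ME, "C21H32O3"),
        (chem.hpepe(8), Derivatization.NONE, "C20H30O4"),
        (chem.hepete(13, (14, 15)), Derivatization.NONE, "C20H30O4"),
        (chem.hepete(13, (14, 15)), ME, "C21H32O4"),
        (chem.keto_epa(), ME, "C21H30O3"),
        (chem.oxo15(), Derivatization.NONE, "C15H20O3"),
    ])
    def test_class_formulas(self, species, deriv, expected):
        assert formula_of(species, deriv).hill() == expected

    def test_epa_is_c20h30o2(self):
        assert EPA.formula.hill() == "C20H30O2"

    def test_class_deltas_relative_to_parent(self):
        """HEPE = EPA+O, HpEPE/HEpETE = EPA+2O, keto = EPA+O-2H."""
        parent = EPA.formula
        assert formula_of(chem.hepe(12)) == parent + ElementalFormula(O=1)
        assert formula_of(chem.hpepe(12)) == parent + ElementalFormula(O=2)
        assert formula_of(chem.hepete(10, (11, 12))) == parent + ElementalFormula(O=2)
        assert (formula_of(chem.keto_epa())
                == parent + ElementalFormula(O=1) - ElementalFormula(H=2))

    @pytest.mark.parametrize("p", [5, 8, 12, 14, 15])
    def test_mass_is_position_independent(self, p):
        assert formula_of(chem.hepe(p)) == formula_of(chem.hepe(15))
        epoxy = chem.HEPETE_PLAN[p]
        assert (formula_of(chem.hepete(epoxy[0], epoxy[1]))
                == formula_of(chem.hepete(13, (14, 15))))

    def test_unknown_marker_has_no_formula(self):
        with pytest.raises(UnsupportedSpeciesError):
            formula_of(chem.unknown_marker("Mk353#1"))


class TestMasses:
    @pytest.mark.parametrize("formula,expected", [
        (ElementalFormula(C=20, H=30, O=2), 302.2246),
        (ElementalFormula(C=21, H=30, O=3), 330.2195),
        (ElementalFormula(), 0.0),
    ])
    def test_monoisotopic_examples(self, formula, expected):
        assert monoisotopic_mass(formula) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("hill", ["C20H30O2", "C21H32O3", "C21H32O4",
                                      "C15H20O3", "C17H34O3", "H2O"])
    def test_against_pyteomics_oracle(self, hill):
        comp = pyteomics_mass.Composition(formula=hill)
        ours = ElementalFormula(C=comp.get("C", 0), H=comp.get("H", 0),
                                O=comp.get("O", 0))
        assert monoisotopic_mass(ours) == pytest.approx(
            pyteomics_mass.calculate_mass(formula=hill), abs=1e-4)

    @given(st.integers(0, 40), st.integers(0, 80), st.integers(0, 10),
           st.integers(0, 40), st.integers(0, 80), st.integers(0, 10))
    def test_additivity(self, c1, h1, o1, c2, h2, o2):
        f1, f2 = ElementalFormula(c1, h1, o1), ElementalFormula(c2, h2, o2)
        assert monoisotopic_mass(f1 + f2) == pytest.approx(
            monoisotopic_mass(f1) + monoisotopic_mass(f2), abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ElementalFormula(C=1) - ElementalFormula(C=2)


class TestAdducts:
    @pytest.mark.parametrize("species,adduct,nominal", [
        (chem.keto_epa(), "M+Na", 353),
        (chem.hepe(15), "M+Na", 355),
        (chem.hepete(13, (14, 15)), "M+Na", 371),
        (chem.hepe(15), "M+H", 333),
    ])
    def test_nominal_mz(self, species, adduct, nominal):
        assert adduct_mz(species, ME, adduct)[1] == nominal

    def test_unsupported_adduct_lists_supported(self):
        with pytest.raises(UnsupportedSpeciesError, match="M\\+H"):
            adduct_mz(chem.hepe(15), ME, "M-H")


class TestNaming:
    @pytest.mark.parametrize("species,name", [
        (chem.hepete(13, (14, 15)), "13,14-HEpETE"),
        (chem.hepete(7, (5, 6)), "7,5-HEpETE"),
        (chem.hepete(10, (8, 9)), "10,8-HEpETE"),
        (chem.hepe(15), "15-HEPE"),
        (chem.hpepe(8), "8-HpEPE"),
        (chem.oxo15(), "15-OXO"),
        (chem.unknown_marker("Mk353#2"), "Mk353#2"),
    ])
    def test_canonical_names(self, species, name):
        assert canonical_name(species) == name

    @pytest.mark.parametrize("name", [
        "5-HEPE", "8-HEPE", "12-HEPE", "15-HEPE",
        "7,5-HEpETE", "10,8-HEpETE", "10,11-HEpETE", "13,14-HEpETE",
        "16,14-HEpETE", "15-OXO", "Mk353#1", "Mk353#2",
    ])
    def test_name_round_trip(self, name):
        """canonical_name(parse_name(x)) == x for the whole compound panel."""
        species = parse_name(name)
        assert canonical_name(species) == name
        if species.cls is not OxylipinClass.UNKNOWN_MARKER:
            assert parse_name(canonical_name(species)) == species

    def test_unparseable_name(self):
        with pytest.raises(ValidationError):
            parse_name("not-a-compound")


class TestValidation:
    def test_hepe_must_not_carry_epoxide(self):
        with pytest.raises(ValidationError, match="epoxide"):
            OxylipinSpecies(cls=OxylipinClass.HEPE, hydroxyl_pos=15,
                            epoxide_pos=(14, 15))

    def test_hepete_requires_vicinal_hydroxyl(self):
        with pytest.raises(ValidationError, match="vicinal"):
            OxylipinSpecies(cls=OxylipinClass.HEPETE, hydroxyl_pos=5,
                            epoxide_pos=(14, 15))

    def test_epoxide_must_be_adjacent_pair(self):
        with pytest.raises(ValidationError):
            OxylipinSpecies(cls=OxylipinClass.HEPETE, hydroxyl_pos=13,
                            epoxide_pos=(14, 16))

    @pytest.mark.parametrize("bonds", [
        ((5, "Z"), (6, "Z")),          # cumulated
        ((8, "Z"), (5, "Z")),          # not increasing
        ((19, "Z"), (25, "Z")),        # outside chain
    ])
    def test_double_bond_invariants(self, bonds):
        with pytest.raises(ValidationError):
            FattyAcid(20, bonds)
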