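"""The reference compound library: expected precursors, ions, UV and RT.

The bundled default library is exactly the observed panel of this genus:
the four HEPEs (5-, 8-, 12-, 15-), the five epoxy-alcohols (7,5-; 10,8-;
10,11-; 13,14-; 16,14-HEpETE), the chain-shortened 15-OXO, the two
undetermined keto-type marker groups (Mk353#1, Mk353#2), and the spiked
internal standard (16-hydroxyhexadecanoic acid, analyzed as methyl ester).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from . import chem, fragmentation
from .chem import (
    Derivatization,
    ElementalFormula,
    FattyAcid,
    OxylipinClass,
    OxylipinSpecies,
    adduct_mz_of_formula,
)
from .constants import (
    MARKER_RT_PAIRS_MIN,
    REFERENCE_RT_MIN,
    UV_CONJUGATED_DIENE_NM,
    UV_KETO_NM,
    UV_OXO_ACID_NM,
)
from .fragmentation import DiagnosticIon

__all__ = ["LibraryEntry", "default_library", "library_to_json",
           "diagnostic_ion_table", "INTERNAL_STANDARD_NAME"]

INTERNAL_STANDARD_NAME = "IS"


@dataclass(frozen=True)
class LibraryEntry:
    """One matchable compound: precursors, diagnostic ions, UV class, RT."""

    name: str
    role: str  # 'oxylipin' | 'marker' | 'internal_standard'
    species: OxylipinSpecies | None
    formula: ElementalFormula | None               # derivatized neutral
    expected_adduct_mzs: dict[str, float]          # adduct -> monoisotopic m/z
    diagnostic_ions: dict[str, tuple[DiagnosticIon, ...]] = field(default_factory=dict)
    uv_class_nm: float | None = None
    reference_rt_min: float | None = None
    marker_rt_pair_min: tuple[float, float] | None = None
    lox_origin: int | None = None

    def ions_for(self, adduct: str) -> tuple[DiagnosticIon, ...]:
        return self.diagnostic_ions.get(adduct, ())


def _mzs(f: ElementalFormula, adducts: tuple[str, ...]) -> dict[str, float]:
    return {a: adduct_mz_of_formula(f, a)[0] for a in adducts}


def default_library(deriv: Derivatization = Derivatization.METHYL_ESTER,
                    adducts: tuple[str, ...] = ("M+Na", "M+H"),
                    h_transfer: int = 1) -> list[LibraryEntry]:
    """Build the bundled compound panel for the given derivatization/adducts."""
    entries: list[LibraryEntry] = []

    for p in (5, 8, 12, 15):
        sp = chem.hepe(p)
        f = chem.formula_of(sp, deriv)
        entries.append(LibraryEntry(
            name=sp.name, role="oxylipin", species=sp, formula=f,
            expected_adduct_mzs=_mzs(f, adducts),
            diagnostic_ions={a: tuple(fragmentation.alpha_cleavage_ions(
                sp, deriv, a, h_transfer)) for a in adducts},
            uv_class_nm=UV_CONJUGATED_DIENE_NM,
            reference_rt_min=REFERENCE_RT_MIN.get(sp.name),
            lox_origin=p,
        ))

    for p in fragmentation.SUPPORTED_LOX_POSITIONS:
        sp = fragmentation.pathway_products(p).primary_epoxy_alcohol
        f = chem.formula_of(sp, deriv)
        entries.append(LibraryEntry(
            name=sp.name, role="oxylipin", species=sp, formula=f,
            expected_adduct_mzs=_mzs(f, adducts),
            diagnostic_ions={a: tuple(fragmentation.diagnostic_ions(
                sp, deriv, a, h_transfer)) for a in adducts},
            uv_class_nm=None,  # no conjugated chromophore
            reference_rt_min=REFERENCE_RT_MIN.get(sp.name),
            lox_origin=p,
        ))

    sp = chem.oxo15()
    f = chem.formula_of(sp, deriv)
    entries.append(LibraryEntry(
        name=sp.name, role="oxylipin", species=sp, formula=f,
        expected_adduct_mzs=_mzs(f, adducts),
        uv_class_nm=UV_OXO_ACID_NM,
        reference_rt_min=REFERENCE_RT_MIN.get(sp.name),
    ))

    # The m/z 353 markers: suggested isomeric keto derivatives of EPA, so the
    # expected precursor is the sodiated keto-EPA methyl ester; no fragments.
    keto_f = chem.formula_of(chem.keto_epa(), deriv)
    for label, rt_pair in MARKER_RT_PAIRS_MIN.items():
        entries.append(LibraryEntry(
            name=label, role="marker", species=chem.unknown_marker(label),
            formula=keto_f,
            expected_adduct_mzs=_mzs(keto_f, ("M+Na",)),
            uv_class_nm=UV_KETO_NM,
            marker_rt_pair_min=rt_pair,
        ))

    # Internal standard: 16-hydroxyhexadecanoic acid methyl ester (C17H34O3).
    is_f = FattyAcid(16).formula + ElementalFormula(O=1) + ElementalFormula(C=1, H=2)
    entries.append(LibraryEntry(
        name=INTERNAL_STANDARD_NAME, role="internal_standard", species=None,
        formula=is_f,
        expected_adduct_mzs=_mzs(is_f, adducts),
        reference_rt_min=REFERENCE_RT_MIN[INTERNAL_STANDARD_NAME],
    ))
    return entries


# --------------------------------------------------------------------------
# Export
# --------------------------------------------------------------------------

def library_to_json(entries: list[LibraryEntry]) -> str:
    """Serialize a library (with its annotated ion block) to JSON text."""
    records = []
    for e in entries:
        rec: dict = {
            "name": e.name,
            "role": e.role,
            "formula": e.formula.hill() if e.formula else None,
            "expected_adduct_mzs": {a: round(mz, 4) for a, mz in e.expected_adduct_mzs.items()},
            "uv_class_nm": e.uv_class_nm,
            "reference_rt_min": e.reference_rt_min,
            "marker_rt_pair_min": e.marker_rt_pair_min,
            "lox_origin": e.lox_origin,
        }
        if e.species is not None and e.species.cls is not OxylipinClass.UNKNOWN_MARKER:
            sp = e.species
            rec["structure"] = {
                "class": sp.cls.value,
                "hydroxyl_pos": sp.hydroxyl_pos,
                "hydroperoxide_pos": sp.hydroperoxide_pos,
                "epoxide_pos": list(sp.epoxide_pos) if sp.epoxide_pos else None,
                "ketone_pos": sp.ketone_pos,
                "chain_length": sp.chain_length,
                "double_bonds": [[p, g] for p, g in sp.alkenes],
            }
        rec["diagnostic_ions"] = {
            adduct: [{"label": ion.label, "mz": round(ion.mz, 4),
                      "formula": ion.formula.hill(),
                      "cleavage_bond": list(ion.cleavage_bond) if ion.cleavage_bond else None,
                      "retained_side": ion.retained_side,
                      "h_transfer": ion.h_transfer}
                     for ion in ions]
            for adduct, ions in e.diagnostic_ions.items()
        }
        records.append(rec)
    return json.dumps(records, indent=2)


def diagnostic_ion_table(entries: list[LibraryEntry]) -> pd.DataFrame:
    """Flat table of every diagnostic ion in the library (for CSV export)."""
    rows = []
    for e in entries:
        for adduct, ions in e.diagnostic_ions.items():
            for ion in ions:
                rows.append({
                    "compound": e.name,
                    "adduct": adduct,
                    "cleavage_bond": (f"C{ion.cleavage_bond[0]}-C{ion.cleavage_bond[1]}"
                                      if ion.cleavage_bond else "neutral loss"),
                    "retained_side": ion.retained_side or "",
                    "formula": ion.formula.hill(),
                    "h_transfer": ion.h_transfer,
                    "mz": round(ion.mz, 4),
                    "label": ion.label,
                })
    return pd.DataFrame(rows)
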