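"""Structural models of EPA-derived oxylipins and their mass arithmetic.

The genus under study channels its oxylipin chemistry through a single
precursor, eicosapentaenoic acid (EPA, 20:5 n-3). A lipoxygenase (LOX)
inserts O2 at one of five carbons (5, 8, 12, 14 or 15, counted from the
carboxyl carbon C1), giving a hydroperoxide (HpEPE) that is either reduced
to the corresponding hydroxy acid (HEPE) or rearranged intramolecularly to
a hydroxy-epoxide (HEpETE). This module models those structures just deeply
enough to compute exact elemental formulas, monoisotopic masses and adduct
m/z values for the methyl-ester derivatives measured by LC-MS/MS.

Carbon numbering starts at the carboxyl carbon (C1) throughout, as in the
compound names ("15-HEPE" = hydroxyl on C15). Double-bond geometry is kept
for naming fidelity but plays no role in mass computation.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass

from .constants import (
    ADDUCT_CATION,
    ELECTRON_MASS,
    MONOISOTOPIC_MASS,
    UV_KETO_NM,
)
from .errors import UnsupportedSpeciesError, ValidationError

__all__ = [
    "ElementalFormula",
    "FattyAcid",
    "EPA",
    "OxylipinClass",
    "OxylipinSpecies",
    "Derivatization",
    "formula_of",
    "monoisotopic_mass",
    "adduct_mz",
    "adduct_mz_of_formula",
    "canonical_name",
    "parse_name",
    "hepe",
    "hpepe",
    "hepete",
    "keto_epa",
    "oxo15",
    "unknown_marker",
    "HEPE_DOUBLE_BONDS",
    "HEPETE_PLAN",
]


# --------------------------------------------------------------------------
# Elemental formulas
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementalFormula:
    """Non-negative element counts over {C, H, O, Na}; closed under + and -."""

    C: int = 0
    H: int = 0
    O: int = 0
    Na: int = 0

    def __post_init__(self) -> None:
        for el in ("C", "H", "O", "Na"):
            n = getattr(self, el)
            if not isinstance(n, int) or n < 0:
                raise ValidationError(f"element count {el}={n!r} must be a non-negative integer")

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(self.C + other.C, self.H + other.H,
                                self.O + other.O, self.Na + other.Na)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(self.C - other.C, self.H - other.H,
                                self.O - other.O, self.Na - other.Na)

    def as_dict(self) -> dict[str, int]:
        return {el: n for el in ("C", "H", "O", "Na") if (n := getattr(self, el))}

    def hill(self) -> str:
        """Hill-notation string, e.g. 'C21H30O3'."""
        parts = []
        for el in ("C", "H", "O", "Na"):
            n = getattr(self, el)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Exact monoisotopic mass (Da): dot product with the pinned atom masses."""
    return sum(getattr(f, el) * m for el, m in MONOISOTOPIC_MASS.items())


_H2 = ElementalFormula(H=2)
_O1 = ElementalFormula(O=1)
_CH2 = ElementalFormula(C=1, H=2)


# --------------------------------------------------------------------------
# Fatty acids
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FattyAcid:
    """A straight-chain fatty acid: carbon count plus an ordered alkene list.

    ``double_bonds`` holds ``(position, geometry)`` pairs where ``position``
    is the lower carbon of the C=C and geometry is ``"Z"`` or ``"E"``.
    """

    n_carbons: int
    double_bonds: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.n_carbons < 2:
            raise ValidationError(f"n_carbons={self.n_carbons} must be >= 2")
        prev = 0
        for pos, geom in self.double_bonds:
            if not (1 < pos < self.n_carbons):
                raise ValidationError(f"double_bonds position {pos} outside 1 < pos < {self.n_carbons}")
            if geom not in ("Z", "E"):
                raise ValidationError(f"double_bonds geometry {geom!r} must be 'Z' or 'E'")
            if pos <= prev:
                raise ValidationError("double_bonds positions must be strictly increasing")
            if prev and pos == prev + 1:
                raise ValidationError(f"double_bonds at {prev},{pos} are cumulated")
            prev = pos

    @property
    def formula(self) -> ElementalFormula:
        """CnH(2n-2d)O2 for a chain with d C=C plus the carboxyl group."""
        n, d = self.n_carbons, len(self.double_bonds)
        return ElementalFormula(C=n, H=2 * n - 2 * d, O=2)


#: Eicosapentaenoic acid, 20:5 n-3 — the sole oxylipin precursor modeled here.
EPA = FattyAcid(20, ((5, "Z"), (8, "Z"), (11, "Z"), (14, "Z"), (17, "Z")))


# --------------------------------------------------------------------------
# Oxylipin species
# --------------------------------------------------------------------------

class OxylipinClass(enum.Enum):
    HEPE = "HEPE"                     # hydroxy-EPA, parent + O
    HPEPE = "HpEPE"                   # hydroperoxy-EPA, parent + 2O
    HEPETE = "HEpETE"                 # hydroxy-epoxy-ETE, parent + 2O
    OXO_ACID = "OXO_ACID"             # chain-shortened terminal oxo acid
    KETO_PUFA = "KETO_PUFA"           # full-chain keto derivative, parent + O - 2H
    UNKNOWN_MARKER = "UNKNOWN_MARKER"  # structure undetermined; observed mass + UV only


class Derivatization(enum.Enum):
    """Pre-analysis derivatization; the methyl ester replaces the acidic H by CH3."""

    NONE = "none"
    METHYL_ESTER = "methyl_ester"


# Observed alkene patterns of the HEPEs (conjugated diene formed during
# lipoxygenation shifts one parent double bond to E).
HEPE_DOUBLE_BONDS: dict[int, tuple[tuple[int, str], ...]] = {
    5: ((6, "E"), (8, "Z"), (11, "Z"), (14, "Z"), (17, "Z")),
    8: ((5, "Z"), (9, "E"), (11, "Z"), (14, "Z"), (17, "Z")),
    12: ((5, "Z"), (8, "Z"), (10, "E"), (14, "Z"), (17, "Z")),
    14: ((5, "Z"), (8, "Z"), (11, "Z"), (15, "E"), (17, "Z")),
    15: ((5, "Z"), (8, "Z"), (11, "Z"), (13, "E"), (17, "Z")),
}

# For each LOX position: (hydroxyl carbon, epoxide pair, residual alkenes) of
# the epoxy-alcohol observed for that position. The epoxide pair is stored
# (lower, lower+1); short names cite the lower epoxide carbon.
HEPETE_PLAN: dict[int, tuple[int, tuple[int, int], tuple[tuple[int, str], ...]]] = {
    15: (13, (14, 15), ((5, "Z"), (8, "Z"), (11, "Z"), (17, "Z"))),
    14: (16, (14, 15), ((5, "Z"), (8, "Z"), (11, "Z"), (17, "Z"))),
    12: (10, (11, 12), ((5, "Z"), (8, "Z"), (14, "Z"), (17, "Z"))),
    8: (10, (8, 9), ((5, "Z"), (11, "Z"), (14, "Z"), (17, "Z"))),
    5: (7, (5, 6), ((8, "Z"), (11, "Z"), (14, "Z"), (17, "Z"))),
}

_OXO15_DOUBLE_BONDS: tuple[tuple[int, str], ...] = ((5, "Z"), (9, "E"), (11, "E"), (13, "E"))


@dataclass(frozen=True)
class OxylipinSpecies:
    """One structurally defined (or, for markers, mass-defined) oxylipin.

    Exactly the positional fields demanded by ``cls`` may be set; everything
    is validated at construction so downstream code never sees an
    inconsistent species.
    """

    cls: OxylipinClass
    parent: FattyAcid = EPA
    hydroxyl_pos: int | None = None
    hydroperoxide_pos: int | None = None
    epoxide_pos: tuple[int, int] | None = None
    ketone_pos: int | None = None
    chain_truncation: int | None = None
    double_bonds: tuple[tuple[int, str], ...] | None = None
    marker_label: str | None = None
    observed_nominal_mz: int | None = None
    uv_class_nm: float | None = None
    lox_origin: int | None = None

    def __post_init__(self) -> None:
        required = {
            OxylipinClass.HEPE: ("hydroxyl_pos",),
            OxylipinClass.HPEPE: ("hydroperoxide_pos",),
            OxylipinClass.HEPETE: ("hydroxyl_pos", "epoxide_pos"),
            OxylipinClass.KETO_PUFA: ("ketone_pos",),
            OxylipinClass.OXO_ACID: ("ketone_pos", "chain_truncation"),
            OxylipinClass.UNKNOWN_MARKER: ("marker_label", "observed_nominal_mz"),
        }[self.cls]
        positional = ("hydroxyl_pos", "hydroperoxide_pos", "epoxide_pos",
                      "ketone_pos", "chain_truncation", "marker_label",
                      "observed_nominal_mz")
        for fld in positional:
            val = getattr(self, fld)
            if fld in required and val is None:
                raise ValidationError(f"{self.cls.value} requires field {fld}")
            if fld not in required and val is not None:
                raise ValidationError(f"{self.cls.value} must not set field {fld}")
        n = self.chain_length
        for fld in ("hydroxyl_pos", "hydroperoxide_pos", "ketone_pos"):
            val = getattr(self, fld)
            if val is not None and not (1 <= val <= n):
                raise ValidationError(f"{fld}={val} outside chain of {n} carbons")
        if self.epoxide_pos is not None:
            a, b = self.epoxide_pos
            if b != a + 1 or not (1 <= a and b <= n):
                raise ValidationError(f"epoxide_pos={self.epoxide_pos} must be adjacent carbons within the chain")
            if self.hydroxyl_pos not in (a - 1, b + 1):
                raise ValidationError("HEpETE hydroxyl must be vicinal to the epoxide")
        if self.double_bonds is not None:
            # Re-use FattyAcid's validation for the product's own alkene list.
            FattyAcid(n, self.double_bonds)

    @property
    def chain_length(self) -> int:
        return self.chain_truncation if self.chain_truncation is not None else self.parent.n_carbons

    @property
    def alkenes(self) -> tuple[tuple[int, str], ...]:
        if self.double_bonds is not None:
            return self.double_bonds
        return self.parent.double_bonds

    @property
    def name(self) -> str:
        return canonical_name(self)


def canonical_name(species: OxylipinSpecies) -> str:
    """Short field name: '15-HEPE', '13,14-HEpETE', '15-OXO', 'Mk353#1', ..."""
    c = species.cls
    if c is OxylipinClass.HEPE:
        return f"{species.hydroxyl_pos}-HEPE"
    if c is OxylipinClass.HPEPE:
        return f"{species.hydroperoxide_pos}-HpEPE"
    if c is OxylipinClass.HEPETE:
        return f"{species.hydroxyl_pos},{species.epoxide_pos[0]}-HEpETE"
    if c is OxylipinClass.OXO_ACID:
        return f"{species.ketone_pos}-OXO"
    if c is OxylipinClass.KETO_PUFA:
        return f"{species.ketone_pos}-keto-EPA"
    return species.marker_label  # UNKNOWN_MARKER


# --------------------------------------------------------------------------
# Species constructors
# --------------------------------------------------------------------------

def hepe(position: int) -> OxylipinSpecies:
    """Hydroxy-EPA with the hydroxyl at ``position``."""
    return OxylipinSpecies(
        cls=OxylipinClass.HEPE,
        hydroxyl_pos=position,
        double_bonds=HEPE_DOUBLE_BONDS.get(position),
        lox_origin=position,
    )


def hpepe(position: int) -> OxylipinSpecies:
    """Hydroperoxy-EPA, the primary LOX product at ``position``."""
    return OxylipinSpecies(
        cls=OxylipinClass.HPEPE,
        hydroperoxide_pos=position,
        double_bonds=HEPE_DOUBLE_BONDS.get(position),
        lox_origin=position,
    )


def hepete(hydroxyl: int, epoxide: tuple[int, int],
           double_bonds: tuple[tuple[int, str], ...] | None = None,
           lox_origin: int | None = None) -> OxylipinSpecies:
    """Hydroxy-epoxy-eicosatetraenoic acid (epoxy-alcohol)."""
    if double_bonds is None or lox_origin is None:
        for p, (h, e, dbs) in HEPETE_PLAN.items():
            if h == hydroxyl and e == tuple(epoxide):
                double_bonds = double_bonds if double_bonds is not None else dbs
                lox_origin = lox_origin if lox_origin is not None else p
                break
    return OxylipinSpecies(
        cls=OxylipinClass.HEPETE,
        hydroxyl_pos=hydroxyl,
        epoxide_pos=tuple(epoxide),
        double_bonds=double_bonds,
        lox_origin=lox_origin,
    )


def keto_epa(ketone_pos: int = 15) -> OxylipinSpecies:
    """A mono-keto full-chain EPA derivative (C20H28O3 as the free acid).

    The ketone position does not affect the formula; it matters only for
    naming, so the hypothetical marker parent may use any position.
    """
    return OxylipinSpecies(cls=OxylipinClass.KETO_PUFA, ketone_pos=ketone_pos)


def oxo15() -> OxylipinSpecies:
    """15-oxo-5Z,9E,11E,13E-pentadecatetraenoic acid, the chain-shortened oxo acid."""
    return OxylipinSpecies(
        cls=OxylipinClass.OXO_ACID,
        ketone_pos=15,
        chain_truncation=15,
        double_bonds=_OXO15_DOUBLE_BONDS,
    )


def unknown_marker(label: str, nominal_mz: int = 353,
                   uv_nm: float = UV_KETO_NM) -> OxylipinSpecies:
    """Structurally undetermined marker known only by precursor m/z and UV class."""
    return OxylipinSpecies(
        cls=OxylipinClass.UNKNOWN_MARKER,
        marker_label=label,
        observed_nominal_mz=nominal_mz,
        uv_class_nm=uv_nm,
    )


# --------------------------------------------------------------------------
# Formula and m/z arithmetic
# --------------------------------------------------------------------------

def formula_of(species: OxylipinSpecies,
               deriv: Derivatization = Derivatization.NONE) -> ElementalFormula:
    """Elemental formula of a (possibly derivatized) oxylipin.

    Built from the species' own chain (length, alkene count) plus group
    deltas: +O per hydroxyl/ketone, +2O per hydroperoxide, +O-2H per epoxide
    ring, -2H per ketone, +CH2 for the methyl ester.
    """
    if species.cls is OxylipinClass.UNKNOWN_MARKER:
        raise UnsupportedSpeciesError(
            f"{species.marker_label}: structure undetermined, no formula can be derived")
    base = FattyAcid(species.chain_length, species.alkenes).formula
    c = species.cls
    if c is OxylipinClass.HEPE:
        f = base + _O1
    elif c is OxylipinClass.HPEPE:
        f = base + _O1 + _O1
    elif c is OxylipinClass.HEPETE:
        f = base + _O1 + _O1 - _H2  # hydroxyl + epoxide ring
    elif c in (OxylipinClass.KETO_PUFA, OxylipinClass.OXO_ACID):
        f = base + _O1 - _H2
    else:  # pragma: no cover - enum is exhaustive
        raise UnsupportedSpeciesError(f"unsupported class {c}")
    if deriv is Derivatization.METHYL_ESTER:
        f = f + _CH2
    return f


def adduct_mz_of_formula(f: ElementalFormula, adduct: str) -> tuple[float, int]:
    """(monoisotopic m/z, nominal integer m/z) of a singly charged cation adduct."""
    if adduct not in ADDUCT_CATION:
        raise UnsupportedSpeciesError(
            f"unsupported adduct {adduct!r}; supported: {sorted(ADDUCT_CATION)}")
    cation = ElementalFormula(**ADDUCT_CATION[adduct])
    mz = monoisotopic_mass(f + cation) - ELECTRON_MASS
    return mz, round(mz)


def adduct_mz(species: OxylipinSpecies,
              deriv: Derivatization = Derivatization.NONE,
              adduct: str = "M+Na") -> tuple[float, int]:
    """Precursor m/z of a derivatized species for a singly charged adduct."""
    return adduct_mz_of_formula(formula_of(species, deriv), adduct)


# --------------------------------------------------------------------------
# Name parsing (round-trips canonical_name for every library compound)
# --------------------------------------------------------------------------

_NAME_RE = re.compile(
    r"^(?:(?P<h>\d+),(?P<e>\d+)-HEpETE"
    r"|(?P<hepe>\d+)-HEPE"
    r"|(?P<hp>\d+)-HpEPE"
    r"|(?P<oxo>\d+)-OXO"
    r"|(?P<keto>\d+)-keto-EPA"
    r"|(?P<mk>Mk\d+#\d+))$"
)


def parse_name(name: str) -> OxylipinSpecies:
    """Inverse of :func:`canonical_name` for the compound classes modeled here."""
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise ValidationError(f"unparseable oxylipin name {name!r}")
    if m.group("h"):
        e0 = int(m.group("e"))
        return hepete(int(m.group("h")), (e0, e0 + 1))
    if m.group("hepe"):
        return hepe(int(m.group("hepe")))
    if m.group("hp"):
        return hpepe(int(m.group("hp")))
    if m.group("oxo"):
        if int(m.group("oxo")) != 15:
            raise ValidationError(f"only the C15 oxo acid is modeled, got {name!r}")
        return oxo15()
    if m.group("keto"):
        return keto_epa(int(m.group("keto")))
    return unknown_marker(m.group("mk"))
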