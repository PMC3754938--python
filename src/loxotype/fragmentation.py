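"""LOX pathway products and the diagnostic MS/MS ions of epoxy-alcohols.

The positional specificity of a lipoxygenase cannot be read from the mass of
its products: every HEPE weighs the same, as does every HEpETE. What does
encode the position is the MS/MS fragmentation of the epoxy-alcohols. The
C-C bond between the carbinol carbon and its epoxide-adjacent neighbour is
labile; cleaving it splits the chain at a position-specific carbon, so the
two charged fragments (carboxyl side and methyl side) have m/z values unique
to each hydroxyl/epoxide combination. This module generates those ions with
exact elemental bookkeeping and inverts the mapping to rank candidate LOX
positions for an observed fragment list.

Fragment ion convention: singly charged cation adducts (same cation as the
precursor), with a configurable even-electron hydrogen transfer (default +1 H
to the charged fragment; 0 and -1 supported to match instrument behaviour).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import chem
from .chem import (
    Derivatization,
    ElementalFormula,
    OxylipinClass,
    OxylipinSpecies,
    monoisotopic_mass,
)
from .constants import ADDUCT_CATION, ELECTRON_MASS, MONOISOTOPIC_MASS
from .errors import UnsupportedSpeciesError, ValidationError

__all__ = [
    "SUPPORTED_LOX_POSITIONS",
    "LOXPathway",
    "DiagnosticIon",
    "pathway_products",
    "diagnostic_ions",
    "alpha_cleavage_ions",
    "lox_position_from_ions",
]

#: LOX positional specificities observed in the genus; the model supports no others.
SUPPORTED_LOX_POSITIONS: tuple[int, ...] = (5, 8, 12, 14, 15)

_H_MASS = MONOISOTOPIC_MASS["H"]
_H2O = ElementalFormula(H=2, O=1)
_CH3OH = ElementalFormula(C=1, H=4, O=1)


@dataclass(frozen=True)
class LOXPathway:
    """The product set of one LOX positional specificity on EPA."""

    lox_position: int
    primary_product: OxylipinSpecies      # the hydroperoxide HpEPE(p)
    hepe: OxylipinSpecies                 # reduced product HEPE(p)
    epoxy_alcohols: tuple[OxylipinSpecies, ...]  # observed isomer first

    @property
    def primary_epoxy_alcohol(self) -> OxylipinSpecies:
        return self.epoxy_alcohols[0]

    @property
    def products(self) -> tuple[OxylipinSpecies, ...]:
        return (self.hepe, self.primary_product) + self.epoxy_alcohols


def pathway_products(p: int) -> LOXPathway:
    """HEPE, HpEPE and the observed epoxy-alcohol for LOX position ``p``."""
    if p not in SUPPORTED_LOX_POSITIONS:
        raise ValidationError(
            f"LOX position {p} unsupported; this genus shows only {SUPPORTED_LOX_POSITIONS}")
    hydroxyl, epoxide, dbs = chem.HEPETE_PLAN[p]
    epoxy = chem.hepete(hydroxyl, epoxide, dbs, lox_origin=p)
    return LOXPathway(
        lox_position=p,
        primary_product=chem.hpepe(p),
        hepe=chem.hepe(p),
        epoxy_alcohols=(epoxy,),
    )


@dataclass(frozen=True)
class DiagnosticIon:
    """One predicted fragment ion of a derivatized oxylipin adduct."""

    label: str
    mz: float
    formula: ElementalFormula          # neutral-radical side (or neutral-loss product)
    adduct: str
    cleavage_bond: tuple[int, int] | None = None   # None for neutral losses
    retained_side: str | None = None               # 'carboxyl' | 'methyl' | None
    h_transfer: int = 0


def _carbon_hydrogens(species: OxylipinSpecies) -> list[int]:
    """C-H count per chain carbon (index 0 = C1) after all substitutions."""
    n = species.chain_length
    h = [2] * (n + 1)
    h[1] = 0          # carboxyl carbon
    h[n] = 3          # terminal methyl
    for pos, _geom in species.alkenes:
        h[pos] -= 1
        h[pos + 1] -= 1
    if species.hydroxyl_pos is not None:
        h[species.hydroxyl_pos] -= 1
    if species.hydroperoxide_pos is not None:
        h[species.hydroperoxide_pos] -= 1
    if species.epoxide_pos is not None:
        a, b = species.epoxide_pos
        h[a] -= 1
        h[b] -= 1
    if species.ketone_pos is not None:
        h[species.ketone_pos] -= 2
    if min(h[1:]) < 0:
        raise ValidationError("substitution pattern over-saturates a carbon")
    return h


def _side_formulas(species: OxylipinSpecies, deriv: Derivatization,
                   split_after: int) -> tuple[ElementalFormula, ElementalFormula]:
    """Homolytic split of the C(split_after)-C(split_after+1) bond.

    Returns (carboxyl-side, methyl-side) radical formulas; their sum is
    exactly the neutral precursor formula.
    """
    n = species.chain_length
    if not (1 <= split_after < n):
        raise ValidationError(f"cleavage after C{split_after} outside chain of {n} carbons")
    for pos, _geom in species.alkenes:
        if pos == split_after:
            raise ValidationError(f"cannot cleave the C{pos}=C{pos + 1} double bond")
    if species.epoxide_pos is not None and species.epoxide_pos[0] == split_after:
        raise ValidationError("cannot cleave through the epoxide ring")

    h = _carbon_hydrogens(species)

    def side(lo: int, hi: int) -> ElementalFormula:
        f = ElementalFormula(C=hi - lo + 1, H=sum(h[lo:hi + 1]))
        if lo == 1:  # carboxyl group oxygens (+ acidic H or ester methyl)
            f = f + ElementalFormula(O=2)
            if deriv is Derivatization.METHYL_ESTER:
                f = f + ElementalFormula(C=1, H=3)
            else:
                f = f + ElementalFormula(H=1)
        for pos, extra in ((species.hydroxyl_pos, ElementalFormula(O=1, H=1)),
                           (species.hydroperoxide_pos, ElementalFormula(O=2, H=1)),
                           (species.ketone_pos, ElementalFormula(O=1))):
            if pos is not None and lo <= pos <= hi:
                f = f + extra
        if species.epoxide_pos is not None and lo <= species.epoxide_pos[0] <= hi:
            f = f + ElementalFormula(O=1)
        return f

    return side(1, split_after), side(split_after + 1, n)


def _cation_mz(neutral: ElementalFormula, adduct: str, extra_h: int = 0) -> float:
    if adduct not in ADDUCT_CATION:
        raise UnsupportedSpeciesError(
            f"unsupported adduct {adduct!r}; supported: {sorted(ADDUCT_CATION)}")
    cation = ElementalFormula(**ADDUCT_CATION[adduct])
    return monoisotopic_mass(neutral + cation) + extra_h * _H_MASS - ELECTRON_MASS


def _cleavage_ions(species: OxylipinSpecies, split_after: int,
                   deriv: Derivatization, adduct: str,
                   h_transfer: int) -> list[DiagnosticIon]:
    carboxyl, methyl = _side_formulas(species, deriv, split_after)
    name = species.name
    bond = (split_after, split_after + 1)
    ions = []
    for side_name, f in (("carboxyl", carboxyl), ("methyl", methyl)):
        ions.append(DiagnosticIon(
            label=f"{name} C{bond[0]}-C{bond[1]} {side_name} [{adduct}]+",
            mz=_cation_mz(f, adduct, extra_h=h_transfer),
            formula=f,
            adduct=adduct,
            cleavage_bond=bond,
            retained_side=side_name,
            h_transfer=h_transfer,
        ))
    return ions


def _neutral_loss_ions(species: OxylipinSpecies, deriv: Derivatization,
                       adduct: str) -> list[DiagnosticIon]:
    precursor = chem.formula_of(species, deriv)
    losses = [("H2O", _H2O)]
    if deriv is Derivatization.METHYL_ESTER:
        losses.append(("CH3OH", _CH3OH))
    name = species.name
    return [DiagnosticIon(
        label=f"{name} [{adduct}-{loss_name}]+",
        mz=_cation_mz(precursor - loss_f, adduct),
        formula=precursor - loss_f,
        adduct=adduct,
    ) for loss_name, loss_f in losses]


def diagnostic_ions(h: OxylipinSpecies,
                    deriv: Derivatization = Derivatization.METHYL_ESTER,
                    adduct: str = "M+Na",
                    h_transfer: int = 1,
                    include_neutral_losses: bool = True) -> list[DiagnosticIon]:
    """Position-diagnostic MS/MS ions of an epoxy-alcohol.

    Emits the two charge-retention variants of the carbinol/epoxide C-C
    cleavage plus (optionally) the H2O and, for methyl esters, CH3OH neutral
    losses of the precursor. The cleavage ions are the informative ones: the
    neutral losses are shared by all isomers.
    """
    if h.cls is not OxylipinClass.HEPETE:
        raise UnsupportedSpeciesError(
            f"diagnostic ions are defined for epoxy-alcohols, not {h.cls.value}")
    if h_transfer not in (-1, 0, 1):
        raise ValidationError(f"h_transfer={h_transfer} must be -1, 0 or +1")
    c = h.hydroxyl_pos
    a, b = h.epoxide_pos
    split_after = c if c == a - 1 else b  # bond between carbinol and epoxide neighbour
    ions = _cleavage_ions(h, split_after, deriv, adduct, h_transfer)
    if include_neutral_losses:
        ions += _neutral_loss_ions(h, deriv, adduct)
    return ions


def alpha_cleavage_ions(species: OxylipinSpecies,
                        deriv: Derivatization = Derivatization.METHYL_ESTER,
                        adduct: str = "M+Na",
                        h_transfer: int = 1,
                        include_neutral_losses: bool = True) -> list[DiagnosticIon]:
    """Carbinol alpha-cleavage ions of a hydroxy acid (HEPE).

    Cleavage of the two single bonds flanking the hydroxyl-bearing carbon,
    charge retained on either side. These locate the hydroxyl and therefore
    distinguish the isobaric HEPEs from one another.
    """
    if species.cls is not OxylipinClass.HEPE:
        raise UnsupportedSpeciesError(
            f"alpha-cleavage ions are defined for hydroxy acids, not {species.cls.value}")
    c = species.hydroxyl_pos
    ions: list[DiagnosticIon] = []
    for split_after in (c - 1, c):
        ions += _cleavage_ions(species, split_after, deriv, adduct, h_transfer)
    if include_neutral_losses:
        ions += _neutral_loss_ions(species, deriv, adduct)
    return ions


def lox_position_from_ions(observed: list[float], tol: float = 0.05,
                           deriv: Derivatization = Derivatization.METHYL_ESTER,
                           adduct: str = "M+Na",
                           h_transfer: int = 1) -> list[tuple[int, int]]:
    """Rank the supported LOX positions by matched diagnostic-ion count.

    Each position's theoretical ion set is that of its observed epoxy-alcohol.
    Positions with zero matches are dropped. Ties are preserved: the returned
    list is sorted by descending match count, then ascending position, and
    equal counts mean the data cannot separate those positions.
    """
    if not observed:
        raise ValidationError("observed fragment list is empty")
    if tol <= 0:
        raise ValidationError(f"tolerance {tol} must be > 0")
    ranking: list[tuple[int, int]] = []
    for p in SUPPORTED_LOX_POSITIONS:
        ions = diagnostic_ions(pathway_products(p).primary_epoxy_alcohol,
                               deriv, adduct, h_transfer)
        n = sum(1 for ion in ions if any(abs(mz - ion.mz) <= tol for mz in observed))
        if n > 0:
            ranking.append((p, n))
    ranking.sort(key=lambda pn: (-pn[1], pn[0]))
    return ranking
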