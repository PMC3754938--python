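"""Feature-to-compound matching by primary analytical indicators (PAIs).

A feature is identified by jointly matching four indicators against a
library entry: precursor m/z (required), MS/MS fragments, UV lambda_max and
retention time. The tiers are:

* ``identified`` - precursor plus at least one diagnostic fragment;
* ``putative`` - precursor (optionally UV/RT) but no fragment evidence,
  e.g. the chain-shortened oxo acid which carries no diagnostic ions;
* ``unknown_marker`` - the keto-type m/z 353 markers: precursor and keto UV
  match but no fragment identification anywhere in the library;
* ``unassigned`` - nothing matched within tolerance.

Epoxy-alcohol identifications propagate a LOX-position call via the
fragment-based ranking; ties are never silently broken.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .config import PipelineConfig
from .chem import OxylipinClass
from .errors import ValidationError
from .fragmentation import lox_position_from_ions
from .library import LibraryEntry, default_library
from .quantify import StrainProfile

__all__ = ["MSFeature", "Confidence", "IdentificationResult",
           "match_feature", "profile_strain"]


@dataclass(frozen=True)
class MSFeature:
    """One integrated LC-MS feature with its linked MS/MS fragment list."""

    feature_id: str
    rt_min: float
    precursor_mz: float
    peak_area: float
    uv_lambda_max_nm: float | None = None
    assumed_adduct: str | None = None
    fragments: tuple[tuple[float, float], ...] = ()  # (m/z, relative intensity)

    def __post_init__(self) -> None:
        if self.rt_min < 0:
            raise ValidationError(f"feature {self.feature_id}: rt_min={self.rt_min} must be >= 0")
        if self.precursor_mz <= 0:
            raise ValidationError(
                f"feature {self.feature_id}: precursor_mz={self.precursor_mz} must be > 0")
        if self.peak_area < 0:
            raise ValidationError(
                f"feature {self.feature_id}: peak_area={self.peak_area} must be >= 0")
        for mz, inten in self.fragments:
            if mz <= 0 or inten < 0:
                raise ValidationError(
                    f"feature {self.feature_id}: fragments entry ({mz}, {inten}) invalid")


class Confidence(enum.Enum):
    IDENTIFIED = "identified"
    PUTATIVE = "putative"
    UNKNOWN_MARKER = "unknown_marker"
    UNASSIGNED = "unassigned"


@dataclass
class IdentificationResult:
    feature_id: str
    confidence: Confidence
    matched_entry: LibraryEntry | None = None
    matched_adduct: str | None = None
    matched_indicators: frozenset[str] = frozenset()
    n_matched_fragments: int = 0
    precursor_error_da: float | None = None
    lox_call: int | None = None
    lox_ranking: tuple[tuple[int, int], ...] = ()
    mk_group: str | None = None

    @property
    def compound_label(self) -> str | None:
        """The row label this result contributes to the quantification matrix."""
        if self.confidence is Confidence.UNASSIGNED or self.matched_entry is None:
            return None
        if self.confidence is Confidence.UNKNOWN_MARKER:
            return self.mk_group
        return self.matched_entry.name


@dataclass
class _Candidate:
    entry: LibraryEntry
    order: int
    adduct: str
    precursor_error_da: float
    indicators: frozenset[str]
    n_fragments: int

    @property
    def score(self) -> tuple:
        # most indicators, then most fragments, then smallest precursor error;
        # library order as the final, deterministic tie-break
        return (len(self.indicators), self.n_fragments,
                -abs(self.precursor_error_da), -self.order)


def _reference_rts(entry: LibraryEntry) -> tuple[float, ...]:
    if entry.marker_rt_pair_min is not None:
        return entry.marker_rt_pair_min
    if entry.reference_rt_min is not None:
        return (entry.reference_rt_min,)
    return ()


def _evaluate(f: MSFeature, entry: LibraryEntry, order: int,
              cfg: PipelineConfig) -> _Candidate | None:
    adducts = (f.assumed_adduct,) if f.assumed_adduct else cfg.adducts
    best: tuple[float, str] | None = None
    for adduct in adducts:
        if adduct not in entry.expected_adduct_mzs:
            continue
        err = f.precursor_mz - entry.expected_adduct_mzs[adduct]
        if abs(err) <= cfg.precursor_tol_da and (best is None or abs(err) < abs(best[0])):
            best = (err, adduct)
    if best is None:
        return None
    err, adduct = best
    indicators = {"precursor"}
    n_frag = 0
    theoretical = entry.ions_for(adduct)
    if theoretical and f.fragments:
        observed = [mz for mz, _ in f.fragments]
        n_frag = sum(1 for ion in theoretical
                     if any(abs(mz - ion.mz) <= cfg.fragment_tol_da for mz in observed))
        if n_frag:
            indicators.add("fragments")
    if entry.uv_class_nm is not None and f.uv_lambda_max_nm is not None:
        if abs(f.uv_lambda_max_nm - entry.uv_class_nm) <= cfg.uv_tol_nm:
            indicators.add("uv")
    if cfg.rt_reference:
        refs = _reference_rts(entry)
        if refs and min(abs(f.rt_min - r) for r in refs) <= cfg.rt_tol_min:
            indicators.add("rt")
    return _Candidate(entry, order, adduct, err, frozenset(indicators), n_frag)


def _mk_group(f: MSFeature, entry: LibraryEntry, candidates: list[_Candidate],
              cfg: PipelineConfig) -> str:
    """Assign a marker group by nearest isomer RT, or declare it unresolved."""
    if not cfg.rt_reference:
        return "353-unresolved"
    centers = [(abs(f.rt_min - rt), c.entry.name)
               for c in candidates if c.entry.role == "marker"
               for rt in (c.entry.marker_rt_pair_min or ())]
    centers += [(abs(f.rt_min - rt), entry.name)
                for rt in (entry.marker_rt_pair_min or ())]
    d, name = min(centers)
    return name if d <= cfg.mk_rt_window_min else "353-unresolved"


def match_feature(f: MSFeature, lib: list[LibraryEntry],
                  cfg: PipelineConfig | None = None) -> IdentificationResult:
    """Match one feature against the library by primary analytical indicators."""
    if not lib:
        raise ValidationError("library is empty")
    cfg = cfg or PipelineConfig()
    candidates = [c for i, e in enumerate(lib) if (c := _evaluate(f, e, i, cfg))]
    if not candidates:
        return IdentificationResult(f.feature_id, Confidence.UNASSIGNED)

    with_frag = [c for c in candidates if c.n_fragments > 0]
    if with_frag:
        best = max(with_frag, key=lambda c: c.score)
        lox_call = None
        ranking: tuple[tuple[int, int], ...] = ()
        sp = best.entry.species
        if sp is not None and sp.cls is OxylipinClass.HEPETE:
            rank = lox_position_from_ions(
                [mz for mz, _ in f.fragments], cfg.fragment_tol_da,
                adduct=best.adduct, h_transfer=cfg.h_transfer)
            ranking = tuple(rank)
            if rank and (len(rank) == 1 or rank[0][1] > rank[1][1]):
                lox_call = rank[0][0]
        return IdentificationResult(
            f.feature_id, Confidence.IDENTIFIED, best.entry, best.adduct,
            best.indicators, best.n_fragments, best.precursor_error_da,
            lox_call=lox_call, lox_ranking=ranking)

    best = max(candidates, key=lambda c: c.score)
    if best.entry.role == "marker" and "uv" in best.indicators:
        group = _mk_group(f, best.entry, candidates, cfg)
        return IdentificationResult(
            f.feature_id, Confidence.UNKNOWN_MARKER, best.entry, best.adduct,
            best.indicators, 0, best.precursor_error_da, mk_group=group)
    return IdentificationResult(
        f.feature_id, Confidence.PUTATIVE, best.entry, best.adduct,
        best.indicators, 0, best.precursor_error_da)


def profile_strain(features: list[MSFeature], lib: list[LibraryEntry] | None = None,
                   cfg: PipelineConfig | None = None, *,
                   strain_id: str = "strain", species_label: str | None = None,
                   replicate: int | None = None) -> StrainProfile:
    """Identify every feature of a strain and aggregate into a profile.

    Compound areas are summed over features mapping to the same compound
    (the marker isomer pairs each contribute two features to one row).
    The internal-standard area is taken from the largest matching feature;
    when absent the profile is flagged and left for deferred normalization.
    """
    cfg = cfg or PipelineConfig()
    lib = lib if lib is not None else default_library(
        adducts=cfg.adducts, h_transfer=cfg.h_transfer)
    results = [match_feature(f, lib, cfg) for f in features]
    profile = StrainProfile(strain_id=strain_id, species_label=species_label,
                            replicate=replicate, identifications=results)

    is_areas = []
    for f, r in zip(features, results):
        if r.matched_entry is not None and r.matched_entry.role == "internal_standard":
            is_areas.append(f.peak_area)
            continue
        label = r.compound_label
        if label is None:
            continue
        profile.compound_areas[label] = profile.compound_areas.get(label, 0.0) + f.peak_area
        if r.lox_call is not None:
            profile.lox_positions.add(r.lox_call)
        if r.confidence is Confidence.UNKNOWN_MARKER and r.mk_group != "353-unresolved":
            profile.marker_groups.add(r.mk_group)
        sp = r.matched_entry.species
        if sp is not None and sp.cls is OxylipinClass.OXO_ACID:
            profile.oxo_present = True
    if is_areas:
        profile.is_area = max(is_areas)
    else:
        profile.missing_internal_standard = True
    return profile
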