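"""The in-study species panel: chemotypes and a text-derived rbcL topology.

``PANEL_CHEMOTYPES`` encodes the reported per-species oxylipin panels:
15-/12-LOX in P. arenysensis (with occasional 15-OXO), 5-LOX plus the
Mk353#1 marker pair in P. delicatissima, 8-LOX plus Mk353#2 in
P. pseudodelicatissima, 14-LOX in P. fraudulenta and P. multistriata,
Mk353#2 alone in P. cf. delicatissima (new genotype) and P. multiseries,
and no unequivocal oxylipins in P. galaxiae.

``rbcl_tree()`` loads a SYNTHETIC transcription of the published rbcL
topology, reconstructed from its textual description (basal
P. turgiduloides; a fraudulenta clade; multistriata sister to
multiseries+pungens; galaxiae sister to the delicatissima superclade whose
apical trio groups pseudodelicatissima, the new genotype and
delicatissima). Nodes whose arrangement the text leaves open are kept as
polytomies. It is an approximation of the figure, not the figure itself.
"""

from __future__ import annotations

from importlib import resources

import dendropy

from .phylo import Chemotype, load_tree

__all__ = ["PANEL_CHEMOTYPES", "ALL_TIPS", "rbcl_tree", "rbcl_tree_path",
           "marker_character", "lox_character"]

PANEL_CHEMOTYPES: dict[str, Chemotype] = {
    "P_arenysensis": Chemotype(lox_positions=frozenset({15, 12}), oxo_present=True),
    "P_delicatissima": Chemotype(lox_positions=frozenset({5}),
                                 marker_groups=frozenset({"Mk353#1"})),
    "P_pseudodelicatissima": Chemotype(lox_positions=frozenset({8}),
                                       marker_groups=frozenset({"Mk353#2"})),
    "P_cf_delicatissima_new": Chemotype(marker_groups=frozenset({"Mk353#2"})),
    "P_multiseries": Chemotype(marker_groups=frozenset({"Mk353#2"})),
    "P_fraudulenta": Chemotype(lox_positions=frozenset({14})),
    "P_multistriata": Chemotype(lox_positions=frozenset({14})),
    "P_galaxiae": Chemotype(empty=True),
}

#: every tip of the fixture topology (three tips were not chemically profiled)
ALL_TIPS: tuple[str, ...] = (
    "P_turgiduloides", "P_fraudulenta", "P_multistriata", "P_multiseries",
    "P_pungens", "P_galaxiae", "P_pseudodelicatissima", "P_cf_delicatissima_new",
    "P_delicatissima", "P_dolorosa", "P_arenysensis",
)

OUTGROUP = "P_turgiduloides"


def rbcl_tree_path() -> str:
    return str(resources.files("loxotype").joinpath(
        "data", "rbcl_topology_text_derived.nwk"))


def rbcl_tree() -> dendropy.Tree:
    """The transcribed rbcL topology, rooted on the basal P. turgiduloides."""
    return load_tree(rbcl_tree_path(), rooted=True)


def marker_character(group: str,
                     chemotypes: dict[str, Chemotype] | None = None) -> dict[str, int]:
    """Binary tip character: presence of a marker group on the fixture tips."""
    chemotypes = chemotypes if chemotypes is not None else PANEL_CHEMOTYPES
    return {tip: int(group in chemotypes.get(tip, Chemotype(empty=True)).marker_groups)
            for tip in ALL_TIPS}


def lox_character(position: int,
                  chemotypes: dict[str, Chemotype] | None = None) -> dict[str, int]:
    """Binary tip character: presence of a LOX positional specificity."""
    chemotypes = chemotypes if chemotypes is not None else PANEL_CHEMOTYPES
    return {tip: int(position in chemotypes.get(tip, Chemotype(empty=True)).lox_positions)
            for tip in ALL_TIPS}
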