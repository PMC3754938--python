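"""Chemotype characters on phylogenies: Fitch and Dollo parsimony.

Chemotypes (the set of LOX positional specificities plus marker groups per
taxon) are treated as discrete characters on an input tree. Two parsimony
quantities are computed:

* ``fitch_min_changes`` - the minimum number of state changes of a
  (binary or small multistate) character on the given topology, allowing
  free transitions in both directions. Implemented as unit-cost dynamic
  programming over the nodes, which is exact on multifurcating trees
  (the classic two-set rule is not).

* ``dollo_min_gains`` - the minimum number of independent acquisitions
  (0 -> 1 transitions) of a binary character when the ancestral root state
  is absence and the character, once present, may not be regained after a
  loss in the same lineage. With losses disallowed this is the number of
  maximal all-present clades; on polytomies the count is minimized over all
  binary resolutions (all-present children of a mixed node can always be
  grouped under a single gain). The complementary single-gain scenario -
  one acquisition at the most recent common ancestor of the present tips,
  followed by losses - is quantified by :func:`single_gain_min_losses`.

Branch lengths are ignored throughout; trees are consumed as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from .errors import TreeError, ValidationError
from .quantify import StrainProfile

__all__ = [
    "Chemotype", "CharacterMap", "ChemotypeCensus",
    "load_tree", "assign_chemotype",
    "fitch_min_changes", "dollo_min_gains", "dollo_gain_range",
    "single_gain_min_losses", "map_character",
    "count_chemotypes", "census_from_chemotypes",
    "annotated_newick",
]


# --------------------------------------------------------------------------
# Chemotypes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Chemotype:
    """Presence/absence summary of LOX positions and marker groups for a taxon."""

    lox_positions: frozenset[int] = frozenset()
    marker_groups: frozenset[str] = frozenset()
    oxo_present: bool = False
    empty: bool = False

    def __post_init__(self) -> None:
        if self.empty and (self.lox_positions or self.marker_groups or self.oxo_present):
            raise ValidationError("an empty chemotype cannot carry compounds")


def assign_chemotype(profile: StrainProfile) -> Chemotype:
    """Chemotype of one processed strain profile.

    ``empty`` is true iff the profile contains no unequivocally identified
    compound at all (no LOX call, no marker group, no oxo acid, no compound
    rows).
    """
    if not profile.compound_areas:
        return Chemotype(empty=True)
    return Chemotype(
        lox_positions=frozenset(profile.lox_positions),
        marker_groups=frozenset(profile.marker_groups),
        oxo_present=profile.oxo_present,
    )


@dataclass
class ChemotypeCensus:
    """Species-level chemotype enumeration."""

    n_lox_chemotypes: int
    lox_chemotypes: set[frozenset[int]]
    n_marker_only: int
    table: pd.DataFrame


def census_from_chemotypes(chemotypes: dict[str, Chemotype]) -> ChemotypeCensus:
    """Count distinct non-empty LOX chemotypes over a species -> chemotype map.

    Marker-only chemotypes (no LOX positions but markers present) are counted
    separately, as the census distinguishes positional chemotypes from the
    undetermined marker groups.
    """
    lox_sets = {c.lox_positions for c in chemotypes.values() if c.lox_positions}
    n_marker_only = sum(1 for c in chemotypes.values()
                        if not c.lox_positions and c.marker_groups)
    rows = [{
        "species": sp,
        "lox_positions": ",".join(map(str, sorted(c.lox_positions))),
        "marker_groups": ",".join(sorted(c.marker_groups)),
        "oxo_present": c.oxo_present,
        "empty": c.empty,
    } for sp, c in chemotypes.items()]
    return ChemotypeCensus(
        n_lox_chemotypes=len(lox_sets),
        lox_chemotypes=lox_sets,
        n_marker_only=n_marker_only,
        table=pd.DataFrame(rows),
    )


def count_chemotypes(profiles: list[StrainProfile]) -> ChemotypeCensus:
    """Species-level census over strain profiles (strains of a species unioned)."""
    if not profiles:
        raise ValidationError("no profiles given")
    by_species: dict[str, dict] = {}
    for p in profiles:
        key = p.species_label or p.strain_id
        agg = by_species.setdefault(key, {"lox": set(), "mk": set(), "oxo": False,
                                          "any": False})
        c = assign_chemotype(p)
        agg["lox"] |= c.lox_positions
        agg["mk"] |= c.marker_groups
        agg["oxo"] |= c.oxo_present
        agg["any"] |= not c.empty
    chemotypes = {
        sp: (Chemotype(frozenset(a["lox"]), frozenset(a["mk"]), a["oxo"])
             if a["any"] else Chemotype(empty=True))
        for sp, a in by_species.items()
    }
    return census_from_chemotypes(chemotypes)


# --------------------------------------------------------------------------
# Trees
# --------------------------------------------------------------------------

def load_tree(source: str | Path, rooted: bool | None = None) -> dendropy.Tree:
    """Read a Newick tree from a path or a literal string; polytomies allowed."""
    text = None
    p = Path(str(source))
    if p.exists():
        text = p.read_text()
    elif str(source).lstrip().startswith("("):
        text = str(source)
    else:
        raise TreeError(f"tree source {source!r}: no such file and not Newick text")
    try:
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"unreadable Newick: {exc}") from exc
    labels = [t.label for t in tree.taxon_namespace]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def _check_tips(tree: dendropy.Tree, char: dict[str, object]) -> None:
    missing = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter()
                     if leaf.taxon.label not in char)
    if missing:
        raise TreeError(f"tips missing from character map: {missing}")


def _rooted_tree(tree: dendropy.Tree, outgroup: str | None) -> dendropy.Tree:
    if outgroup is not None:
        node = tree.find_node_with_taxon_label(outgroup)
        if node is None:
            raise TreeError(f"outgroup {outgroup!r} not found among tips")
        tree = tree.clone(depth=1)
        node = tree.find_node_with_taxon_label(outgroup)
        tree.to_outgroup_position(node, update_bipartitions=False)
        tree.is_rooted = True
        return tree
    if not tree.is_rooted:
        raise TreeError("tree is unrooted and no outgroup was declared")
    return tree


# --------------------------------------------------------------------------
# Fitch parsimony (exact on polytomies via unit-cost DP)
# --------------------------------------------------------------------------

def fitch_min_changes(tree: dendropy.Tree,
                      char: dict[str, object]) -> tuple[int, dict]:
    """Minimum number of state changes and per-node optimal state sets.

    Unit-cost Sankoff dynamic programming: for each node and state, the
    minimum number of changes in the subtree given that the node takes the
    state. Works for any arity and any (hashable) state alphabet; equals the
    brute-force minimum over all ancestral labelings of the given topology.
    Returns ``(min_changes, node -> frozenset of subtree-optimal states)``.
    """
    _check_tips(tree, char)
    leaves = list(tree.leaf_node_iter())
    if not leaves:
        raise TreeError("tree has no tips")
    states = sorted({char[l.taxon.label] for l in leaves}, key=repr)
    INF = float("inf")
    cost: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s0 = char[node.taxon.label]
            cost[node] = {s: (0 if s == s0 else INF) for s in states}
        else:
            cost[node] = {
                s: sum(min(c[t] + (t != s) for t in states)
                       for child in node.child_nodes()
                       for c in (cost[child],))
                for s in states
            }
    root_costs = cost[tree.seed_node]
    best = min(root_costs.values())
    state_sets = {node: frozenset(s for s, c in cs.items() if c == min(cs.values()))
                  for node, cs in cost.items()}
    return int(best), state_sets


# --------------------------------------------------------------------------
# Dollo parsimony (irreversible gains)
# --------------------------------------------------------------------------

def _binary_char(char: dict[str, object]) -> dict[str, int]:
    out = {}
    for tip, s in char.items():
        if s not in (0, 1, "0", "1", False, True):
            raise ValidationError(f"character state {s!r} at tip {tip!r} is not binary")
        out[tip] = int(s)
    return out


def _dollo_counts(tree: dendropy.Tree, char: dict[str, int]) -> tuple[int, int]:
    """(min over binary resolutions, count with polytomies unresolved)."""
    STATUS_ABSENT, STATUS_PRESENT, STATUS_MIXED = 0, 1, 2
    status: dict = {}
    g_min: dict = {}
    g_unres: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            status[node] = STATUS_PRESENT if char[node.taxon.label] else STATUS_ABSENT
            g_min[node] = g_unres[node] = 0
            continue
        children = node.child_nodes()
        sts = [status[c] for c in children]
        if all(s == STATUS_PRESENT for s in sts):
            status[node] = STATUS_PRESENT
            g_min[node] = g_unres[node] = 0
        elif all(s == STATUS_ABSENT for s in sts):
            status[node] = STATUS_ABSENT
            g_min[node] = g_unres[node] = 0
        else:
            status[node] = STATUS_MIXED
            n_present = sum(1 for s in sts if s == STATUS_PRESENT)
            mixed = [c for c in children if status[c] == STATUS_MIXED]
            # All all-present children of a mixed node can be grouped under
            # one gain in some binary resolution; unresolved, each needs its own.
            g_min[node] = sum(g_min[c] for c in mixed) + (1 if n_present else 0)
            g_unres[node] = sum(g_unres[c] for c in mixed) + n_present
    root = tree.seed_node
    if status[root] == STATUS_PRESENT:
        return 1, 1  # single gain on the root edge
    return g_min[root], g_unres[root]


def dollo_min_gains(tree: dendropy.Tree, char: dict[str, object],
                    outgroup: str | None = None) -> int:
    """Minimum number of independent acquisitions of a binary character.

    The root state is absence; gains are irreversible along a lineage
    (no loss-then-regain), and the reported minimum is taken over all binary
    resolutions of polytomies. The tree must be rooted, or ``outgroup`` must
    name the tip to root on.
    """
    tree = _rooted_tree(tree, outgroup)
    bchar = _binary_char(char)
    _check_tips(tree, bchar)
    return _dollo_counts(tree, bchar)[0]


def dollo_gain_range(tree: dendropy.Tree, char: dict[str, object],
                     outgroup: str | None = None) -> tuple[int, int]:
    """(minimum over polytomy resolutions, count on the unresolved topology).

    The two coincide on strictly binary trees; on polytomies they bracket
    the number of acquisitions the data support.
    """
    tree = _rooted_tree(tree, outgroup)
    bchar = _binary_char(char)
    _check_tips(tree, bchar)
    return _dollo_counts(tree, bchar)


def single_gain_min_losses(tree: dendropy.Tree, char: dict[str, object],
                           outgroup: str | None = None) -> int:
    """Losses required if the character was acquired exactly once.

    The single gain is placed on the edge above the MRCA of the present
    tips; the count is the number of maximal all-absent clades within that
    subtree (each needs one loss). Returns 0 when no tip is present.
    """
    tree = _rooted_tree(tree, outgroup)
    bchar = _binary_char(char)
    _check_tips(tree, bchar)
    present = [leaf for leaf in tree.leaf_node_iter() if bchar[leaf.taxon.label]]
    if not present:
        return 0
    labels = [l.taxon.label for l in present]
    mrca = tree.mrca(taxa=[l.taxon for l in present]) if len(labels) > 1 else present[0]

    def absent_clades(node) -> tuple[bool, int]:
        # returns (all_absent, number of maximal all-absent clades below)
        if node.is_leaf():
            return (bchar[node.taxon.label] == 0, 0)
        results = [absent_clades(c) for c in node.child_nodes()]
        if all(a for a, _ in results):
            return True, 0
        return False, sum(1 if a else n for a, n in results)

    # the MRCA subtree contains present tips, so all_absent is always False here
    _, n_losses = absent_clades(mrca)
    return n_losses


# --------------------------------------------------------------------------
# Character maps and reports
# --------------------------------------------------------------------------

@dataclass
class CharacterMap:
    """One character mapped on a tree, with both parsimony summaries."""

    name: str
    tip_states: dict[str, object]
    min_changes: int
    reconstruction: dict = field(repr=False, default_factory=dict)
    min_gains_dollo: int | None = None
    max_gains_unresolved: int | None = None
    single_gain_losses: int | None = None


def map_character(tree: dendropy.Tree, name: str, tip_states: dict[str, object],
                  outgroup: str | None = None) -> CharacterMap:
    """Fitch reconstruction plus, for binary characters, the Dollo gain counts."""
    min_changes, sets = fitch_min_changes(tree, tip_states)
    cm = CharacterMap(name=name, tip_states=dict(tip_states),
                      min_changes=min_changes, reconstruction=sets)
    try:
        bchar = _binary_char(tip_states)
    except ValidationError:
        return cm
    if any(bchar.values()):
        lo, hi = dollo_gain_range(tree, bchar, outgroup)
        cm.min_gains_dollo = lo
        cm.max_gains_unresolved = hi
        cm.single_gain_losses = single_gain_min_losses(tree, bchar, outgroup)
    return cm


def annotated_newick(tree: dendropy.Tree, reconstruction: dict) -> str:
    """Newick with per-node reconstructed state sets as comment annotations.

    Nodes are matched to the reconstruction by their tip sets, so the
    reconstruction may come from a (rooted) clone of the same tree.
    """
    clone = tree.clone(depth=1)
    by_leafset = {
        frozenset(l.taxon.label for l in node.leaf_iter()): states
        for node, states in reconstruction.items()
    }
    for node in clone.preorder_node_iter():
        key = frozenset(l.taxon.label for l in node.leaf_iter())
        states = by_leafset.get(key)
        if states is not None:
            node.annotations.add_new(
                "states", "|".join(str(s) for s in sorted(states, key=repr)))
    return clone.as_string(schema="newick", suppress_annotations=False,
                           unquoted_underscores=True)
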