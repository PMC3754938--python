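"""Chemotype assignment, Fitch/Dollo parsimony, and the fixture topology."""

import random

import pytest
from oracles import brute_force_dollo, brute_force_fitch, contract_random_edges

from loxotype import panel
from loxotype.errors import TreeError, ValidationError
from loxotype.phylo import (
    Chemotype,
    annotated_newick,
    assign_chemotype,
    census_from_chemotypes,
    count_chemotypes,
    dollo_gain_range,
    dollo_min_gains,
    fitch_min_changes,
    load_tree,
    map_character,
    single_gain_min_losses,
)
from loxotype.quantify import StrainProfile
from loxotype.simulate import simulate_tree


def rooted(newick: str):
    return load_tree(newick, rooted=True)


class TestChemotypes:
    def test_profile_chemotype_fields(self):
        prof = StrainProfile("S", compound_areas={"15-HEPE": 1.0, "Mk353#2": 2.0},
                             lox_positions={15, 12}, marker_groups={"Mk353#2"},
                             oxo_present=True)
        c = assign_chemotype(prof)
        assert c.lox_positions == {15, 12}
        assert c.marker_groups == {"Mk353#2"}
        assert c.oxo_present and not c.empty

    def test_marker_only_profile(self):
        prof = StrainProfile("S", compound_areas={"Mk353#2": 2.0},
                             marker_groups={"Mk353#2"})
        c = assign_chemotype(prof)
        assert c.lox_positions == frozenset()
        assert c.marker_groups == {"Mk353#2"}

    def test_empty_profile_gives_empty_chemotype(self):
        assert assign_chemotype(StrainProfile("S")).empty

    def test_empty_chemotype_cannot_carry_compounds(self):
        with pytest.raises(ValidationError):
            Chemotype(lox_positions=frozenset({5}), empty=True)

    def test_census_counts_distinct_lox_sets(self):
        census = census_from_chemotypes(panel.PANEL_CHEMOTYPES)
        assert census.n_lox_chemotypes >= 4
        assert frozenset({15, 12}) in census.lox_chemotypes
        assert census.n_marker_only == 2  # Mk353#2-only species

    def test_identical_profiles_are_one_chemotype(self):
        profs = [StrainProfile(f"S{i}", species_label=f"sp{i}",
                               compound_areas={"5-HEPE": 1.0}, lox_positions={5})
                 for i in range(3)]
        assert count_chemotypes(profs).n_lox_chemotypes == 1

    def test_disjoint_singletons_are_two_chemotypes(self):
        profs = [StrainProfile("A", species_label="a",
                               compound_areas={"x": 1.0}, lox_positions={5}),
                 StrainProfile("B", species_label="b",
                               compound_areas={"y": 1.0}, lox_positions={8})]
        assert count_chemotypes(profs).n_lox_chemotypes == 2

    def test_strains_of_one_species_are_unioned(self):
        profs = [StrainProfile("A1", species_label="a",
                               compound_areas={"x": 1.0}, lox_positions={15}),
                 StrainProfile("A2", species_label="a",
                               compound_areas={"y": 1.0}, lox_positions={12})]
        census = count_chemotypes(profs)
        assert census.lox_chemotypes == {frozenset({15, 12})}


class TestFitch:
    def test_single_tip_zero_changes(self):
        tree = rooted("(A);")
        assert fitch_min_changes(tree, {"A": 1})[0] == 0

    def test_balanced_four_tip_split(self):
        tree = rooted("((A,B),(C,D));")
        changes, sets = fitch_min_changes(tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert changes == 1

    def test_polytomy_two_vs_two(self):
        """Unresolved 4-way split with 2+2 states needs two changes."""
        tree = rooted("(A,B,C,D);")
        assert fitch_min_changes(tree, {"A": 0, "B": 0, "C": 1, "D": 1})[0] == 2

    def test_missing_tip_listed(self):
        tree = rooted("((A,B),C);")
        with pytest.raises(TreeError, match="C"):
            fitch_min_changes(tree, {"A": 1, "B": 0})

    def test_matches_brute_force_on_random_trees(self):
        rng = random.Random(7)
        for i in range(30):
            n = rng.randint(3, 7)
            tree, _, _ = simulate_tree(n, seed=1000 + i, n_gains=1)
            if rng.random() < 0.5:
                contract_random_edges(tree, rng)
            char = {f"T{j + 1}": rng.randint(0, 1) for j in range(n)}
            assert fitch_min_changes(tree, char)[0] == brute_force_fitch(tree, char)

    def test_multistate_matches_brute_force(self):
        rng = random.Random(11)
        for i in range(10):
            tree, _, _ = simulate_tree(6, seed=2000 + i, n_gains=1)
            char = {f"T{j + 1}": rng.choice("abc") for j in range(6)}
            assert fitch_min_changes(tree, char)[0] == brute_force_fitch(tree, char)


class TestDollo:
    def test_single_clade_single_gain(self):
        tree = rooted("(((A,B),C),D);")
        assert dollo_min_gains(tree, {"A": 1, "B": 1, "C": 0, "D": 0}) == 1

    def test_all_tips_present_one_root_gain(self):
        tree = rooted("((A,B),(C,D));")
        assert dollo_min_gains(tree, {t: 1 for t in "ABCD"}) == 1

    def test_two_separated_clades_two_gains(self):
        tree = rooted("(((A,B),C),((D,E),F));")
        char = {"A": 1, "B": 1, "C": 0, "D": 1, "E": 1, "F": 0}
        assert dollo_min_gains(tree, char) == 2

    def test_polytomy_resolution_can_merge_gains(self):
        """Two present children of a polytomy can share one gain in a resolution."""
        tree = rooted("(A,B,C);")
        char = {"A": 1, "B": 1, "C": 0}
        assert dollo_gain_range(tree, char) == (1, 2)

    def test_unrooted_without_outgroup_rejected(self):
        tree = load_tree("((A,B),(C,D));")
        tree.is_rooted = False
        with pytest.raises(TreeError, match="outgroup"):
            dollo_min_gains(tree, {t: 1 for t in "ABCD"})

    def test_outgroup_rooting(self):
        tree = load_tree("((A,B),(C,D));")
        tree.is_rooted = False
        assert dollo_min_gains(tree, {"A": 1, "B": 0, "C": 0, "D": 0},
                               outgroup="D") == 1

    def test_nonbinary_state_rejected(self):
        tree = rooted("(A,B);")
        with pytest.raises(ValidationError):
            dollo_min_gains(tree, {"A": 2, "B": 0})

    def test_matches_brute_force_on_binary_trees(self):
        for i in range(30):
            n = random.Random(i).randint(2, 7)
            n_gains = random.Random(i + 1).randint(1, 2)
            try:
                tree, char, _ = simulate_tree(n, seed=3000 + i, n_gains=n_gains)
            except ValidationError:
                continue
            assert dollo_min_gains(tree, char) == brute_force_dollo(tree, char)

    def test_unresolved_count_matches_brute_force_on_polytomies(self):
        rng = random.Random(5)
        for i in range(20):
            tree, _, _ = simulate_tree(6, seed=4000 + i, n_gains=1)
            contract_random_edges(tree, rng)
            char = {f"T{j + 1}": rng.randint(0, 1) for j in range(6)}
            if not any(char.values()):
                continue
            _, unresolved = dollo_gain_range(tree, char)
            assert unresolved == brute_force_dollo(tree, char)

    def test_single_gain_loss_count(self):
        tree = rooted("(((A,B),C),D);")
        char = {"A": 1, "B": 0, "C": 1, "D": 0}
        # one gain at the MRCA of A and C implies a loss in B
        assert single_gain_min_losses(tree, char) == 1


class TestFixtureTopology:
    def test_marker2_needs_at_least_two_gains(self):
        """Mk353#2 is scattered across non-sister species: >= 2 acquisitions."""
        tree = panel.rbcl_tree()
        char = panel.marker_character("Mk353#2")
        lo, hi = dollo_gain_range(tree, char)
        assert lo >= 2
        assert hi >= lo

    def test_14_lox_is_single_gain_on_the_grade(self):
        tree = panel.rbcl_tree()
        assert dollo_min_gains(tree, panel.lox_character(14)) >= 1

    def test_map_character_report(self):
        tree = panel.rbcl_tree()
        cm = map_character(tree, "Mk353#2", panel.marker_character("Mk353#2"))
        assert cm.min_gains_dollo >= 2
        assert cm.min_changes >= 2
        assert cm.single_gain_losses is not None and cm.single_gain_losses >= 1
        text = annotated_newick(tree, cm.reconstruction)
        assert "states" in text and "P_multiseries" in text
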