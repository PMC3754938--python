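"""Independent brute-force oracles used by the parsimony tests.

These deliberately share no code with the package: minima are found by
exhaustive enumeration of ancestral labelings on the given topology.
"""

from __future__ import annotations

import itertools


def tree_edges_and_nodes(tree):
    """(internal nodes, tip states placeholder, edge list as (parent, child))."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    edges = [(n.parent_node, n) for n in tree.preorder_node_iter()
             if n.parent_node is not None]
    return internals, edges


def brute_force_fitch(tree, char: dict) -> int:
    """Minimum state changes over all ancestral labelings (any arity)."""
    internals, edges = tree_edges_and_nodes(tree)
    states = sorted({char[l.taxon.label] for l in tree.leaf_node_iter()}, key=repr)

    def label_of(node, assignment):
        if node.is_leaf():
            return char[node.taxon.label]
        return assignment[id(node)]

    best = None
    for combo in itertools.product(states, repeat=len(internals)):
        assignment = {id(n): s for n, s in zip(internals, combo)}
        changes = sum(1 for p, c in edges
                      if label_of(p, assignment) != label_of(c, assignment))
        if best is None or changes < best:
            best = changes
    return best


def brute_force_dollo(tree, char: dict) -> int:
    """Minimum 0->1 edges with an absent ancestor and no 1->0 edge anywhere.

    The ancestral state sits above a virtual root edge, so a root labeled 1
    costs one gain (acquisition before the radiation). This is the
    irreversible-gain minimum on the topology exactly as given (polytomies
    unresolved).
    """
    internals, edges = tree_edges_and_nodes(tree)
    root = tree.seed_node

    def label_of(node, assignment):
        if node.is_leaf():
            return int(char[node.taxon.label])
        return assignment[id(node)]

    best = None
    for combo in itertools.product((0, 1), repeat=len(internals)):
        assignment = {id(n): s for n, s in zip(internals, combo)}
        gains = label_of(root, assignment)  # virtual root edge
        valid = True
        for p, c in edges:
            sp, sc = label_of(p, assignment), label_of(c, assignment)
            if sp == 1 and sc == 0:
                valid = False
                break
            if sp == 0 and sc == 1:
                gains += 1
        if valid and (best is None or gains < best):
            best = gains
    return best


def contract_random_edges(tree, rng, prob: float = 0.4):
    """Collapse random internal edges in place, producing polytomies."""
    for node in list(tree.preorder_internal_node_iter()):
        if node.parent_node is not None and rng.random() < prob:
            parent = node.parent_node
            for child in list(node.child_nodes()):
                node.remove_child(child)
                parent.add_child(child)
            parent.remove_child(node)
    return tree
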