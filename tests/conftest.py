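"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own Fitch machinery: parsimony
lengths are recomputed by enumerating every assignment of states to
internal nodes, and optima over tree space by scoring every topology.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cladecoev import CharacterMatrix, PhyloTree


# --------------------------------------------------------------------------
# Brute-force parsimony oracle
# --------------------------------------------------------------------------

def brute_force_length(tree: PhyloTree, m: CharacterMatrix) -> int:
    """Minimum changes over all internal-state assignments, all characters."""
    return sum(brute_force_column(tree, m.codes[:, j], m.taxa)
               for j in range(m.n_chars))


def brute_force_column(tree: PhyloTree, column: np.ndarray, taxa: list) -> int:
    """Minimum changes for one character by exhaustive assignment."""
    states = sorted(set(int(s) for s in column if s >= 0))
    if len(states) < 2:
        return 0
    tix = {t: i for i, t in enumerate(taxa)}
    internals, leaves, edges = [], [], []

    def walk(node, parent_id):
        nid = id(node)
        if node.is_leaf:
            leaves.append((nid, int(column[tix[node.label]])))
        else:
            internals.append(nid)
        if parent_id is not None:
            edges.append((parent_id, nid))
        for c in node.children:
            walk(c, nid)

    walk(tree.root, None)
    free_leaves = [nid for nid, s in leaves if s < 0]
    fixed = {nid: s for nid, s in leaves if s >= 0}
    best = np.inf
    var_nodes = internals + free_leaves
    for combo in itertools.product(states, repeat=len(var_nodes)):
        assign = dict(zip(var_nodes, combo))
        assign.update(fixed)
        changes = sum(assign[u] != assign[v] for u, v in edges)
        best = min(best, changes)
    return int(best)


def brute_force_mprs(tree: PhyloTree, column: np.ndarray, taxa: list) -> list:
    """All minimum assignments (node-clade -> state), for mapping oracles."""
    states = sorted(set(int(s) for s in column if s >= 0))
    if len(states) < 2:
        return []
    tix = {t: i for i, t in enumerate(taxa)}
    nodes, edges = [], []

    def walk(node, parent_clade):
        if node.is_leaf:
            clade = frozenset([node.label])
            state = int(column[tix[node.label]])
        else:
            clade = frozenset(tree_leaves(node))
            state = None
        nodes.append((clade, state))
        if parent_clade is not None:
            edges.append((parent_clade, clade))
        for c in node.children:
            walk(c, clade)

    def tree_leaves(node):
        if node.is_leaf:
            return [node.label]
        return [x for c in node.children for x in tree_leaves(c)]

    walk(tree.root, None)
    free = [clade for clade, s in nodes if s is None or s < 0]
    fixed = {clade: s for clade, s in nodes if s is not None and s >= 0}
    best, optima = np.inf, []
    for combo in itertools.product(states, repeat=len(free)):
        assign = dict(zip(free, combo))
        assign.update(fixed)
        changes = sum(assign[u] != assign[v] for u, v in edges)
        if changes < best:
            best, optima = changes, [assign]
        elif changes == best:
            optima.append(assign)
    return optima


# --------------------------------------------------------------------------
# Fixtures
# --------------------------------------------------------------------------

@pytest.fixture
def four_taxon():
    """The classic homoplastic quartet: A=0,B=1,C=0,D=1 on ((A,B),(C,D))."""
    tree = PhyloTree.from_newick("((A,B),(C,D));")
    m = CharacterMatrix(["A", "B", "C", "D"], np.array([[0], [1], [0], [1]]))
    return tree, m


@pytest.fixture
def random_binary_matrix():
    def make(n_taxa, n_chars, seed, n_states=2, missing_rate=0.0):
        rng = np.random.default_rng(seed)
        codes = rng.integers(0, n_states, size=(n_taxa, n_chars)).astype(np.int8)
        if missing_rate:
            codes[rng.random(codes.shape) < missing_rate] = -1
        return CharacterMatrix([f"t{i}" for i in range(n_taxa)], codes)

    return make
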