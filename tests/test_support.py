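"""Bootstrap frequencies, Bremer decay and consensus trees."""

import numpy as np
import pytest

from cladecoev import (CharacterMatrix, PhyloTree, SimulationConfig,
                       bootstrap_support, branch_and_bound_search,
                       bremer_support, consensus, exhaustive_search,
                       flag_significant, simulate)
from cladecoev.errors import ContractError
from cladecoev.search import _all_topologies, _Scorer, _tuple_to_phylo


@pytest.fixture
def bremer_matrix():
    """Three congruent characters supporting {A,B}; E is the outgroup."""
    codes = np.tile(np.array([[1], [1], [0], [0], [0]], dtype=np.int8), (1, 3))
    return CharacterMatrix(["A", "B", "C", "D", "E"], codes)


def _oracle_decay(m, outgroup, clade):
    """Bremer decay by scoring all 15 five-taxon topologies."""
    scorer = _Scorer(m)
    best, best_without = np.inf, np.inf
    for t in _all_topologies(m.n_taxa):
        length = float(m.weights @ scorer.steps(t, 0))
        best = min(best, length)
        pt = _tuple_to_phylo(t, 0, m.taxa, outgroup)
        if not pt.contains_split(clade):
            best_without = min(best_without, length)
    return best_without - best


def test_bremer_decay_matches_fifteen_topology_oracle(bremer_matrix):
    res = branch_and_bound_search(bremer_matrix, "E")
    supports = bremer_support(bremer_matrix, "E", res, cap=8)
    clade = frozenset({"A", "B"})
    assert supports[clade] == (3, False)
    assert _oracle_decay(bremer_matrix, "E", clade) == 3


def test_duplicating_characters_doubles_every_finite_decay(bremer_matrix):
    res = branch_and_bound_search(bremer_matrix, "E")
    base = bremer_support(bremer_matrix, "E", res, cap=50)
    doubled_m = CharacterMatrix(
        bremer_matrix.taxa, np.hstack([bremer_matrix.codes,
                                       bremer_matrix.codes]))
    res2 = branch_and_bound_search(doubled_m, "E")
    doubled = bremer_support(doubled_m, "E", res2, cap=50)
    for clade, (decay, capped) in base.items():
        assert not capped
        assert doubled[clade] == (2 * decay, False)


def test_bremer_is_invariant_under_taxon_relabeling(bremer_matrix):
    res = branch_and_bound_search(bremer_matrix, "E")
    base = bremer_support(bremer_matrix, "E", res, cap=8)
    relabel = {"A": "x1", "B": "x2", "C": "x3", "D": "x4", "E": "x5"}
    m2 = CharacterMatrix([relabel[t] for t in bremer_matrix.taxa],
                         bremer_matrix.codes.copy())
    res2 = branch_and_bound_search(m2, "x5")
    other = bremer_support(m2, "x5", res2, cap=8)
    mapped = {frozenset(relabel[t] for t in c): v for c, v in base.items()}
    assert mapped == other


def test_bootstrap_is_deterministic_and_bounded(random_binary_matrix):
    m = random_binary_matrix(7, 15, 4)
    a = bootstrap_support(m, "t0", n_reps=30, seed=9)
    b = bootstrap_support(m, "t0", n_reps=30, seed=9)
    assert a == b
    full = frozenset(m.taxa)
    for clade, pct in a.items():
        assert 0.0 <= pct <= 100.0
        assert clade != full and clade != full - {"t0"}


def test_bootstrap_on_clean_signal_approaches_certainty():
    """Zero-homoplasy data: every generating clade near 100% support."""
    cfg = SimulationConfig(seed=31, n_taxa=12, n_chars=50, homoplasy=0.0)
    tree, m, _ = simulate(cfg)
    boot = bootstrap_support(m, cfg.outgroup, n_reps=200, seed=17)
    rooted = tree.rooted_on(cfg.outgroup)
    n = len(rooted.taxa)
    true_clades = [c for c in rooted.clades()
                   if cfg.outgroup not in c and 2 <= len(c) <= n - 2]
    assert true_clades
    for clade in true_clades:
        assert boot.get(clade, 0.0) >= 95.0


def test_consensus_identity_star_and_majority():
    t1 = PhyloTree.from_newick("(O,((A,B),(C,D)));")
    assert consensus([t1], "strict").topology_key() == t1.topology_key()

    t2 = PhyloTree.from_newick("(O,((A,C),(B,D)));")
    star = consensus([t1, t2], "strict")
    assert star.bipartitions() == frozenset()

    t3 = PhyloTree.from_newick("(O,((A,B),(C,D)));")
    maj = consensus([t1, t2, t3], "majority", cutoff=0.5)
    assert maj.contains_clade({"A", "B"})
    assert not maj.contains_clade({"A", "C"})


def test_consensus_rejects_mixed_taxon_sets():
    t1 = PhyloTree.from_newick("((A,B),C);")
    t2 = PhyloTree.from_newick("((A,B),D);")
    with pytest.raises(ContractError):
        consensus([t1, t2])


@pytest.mark.parametrize("bremer,boot,expected", [
    ((3, False), 80.0, True),   # both thresholds inclusive
    ((2, False), 99.0, False),  # strong bootstrap cannot rescue weak decay
    ((8, False), 79.0, False),  # strong decay cannot rescue weak bootstrap
    ((8, True), 100.0, True),
])
def test_joint_significance_rule(bremer, boot, expected):
    clade = frozenset({"A", "B"})
    table = flag_significant({clade: boot}, {clade: bremer})
    assert table.table.loc[0, "significant"] == expected


def test_clade_in_one_table_only_is_not_significant():
    c1, c2 = frozenset({"A", "B"}), frozenset({"C", "D"})
    table = flag_significant({c1: 99.0}, {c2: (5, False)})
    assert not table.table["significant"].any()
    assert len(table.table) == 2
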