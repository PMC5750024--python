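"""Similarity, clustering, ANOSIM and NMDS over group event vectors."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cladecoev import (CharacterGroupMap, CharacterGroup, anosim,
                       group_event_matrix, group_similarity,
                       kulczynski_similarity, kruskal_stress1, nmds,
                       single_linkage)
from cladecoev.errors import ContractError
from cladecoev.mapping import GroupEventMatrix


def test_kulczynski_worked_examples():
    assert kulczynski_similarity([1, 1, 0], [1, 1, 0]) == 1.0
    assert kulczynski_similarity([1, 0, 0], [0, 1, 1]) == 0.0
    assert kulczynski_similarity([1, 1, 0], [1, 0, 1]) == 0.5  # a=b=c=1


def test_kulczynski_contracts():
    with pytest.raises(ContractError):
        kulczynski_similarity([1, 0], [1, 0, 1])
    with pytest.raises(ContractError):
        kulczynski_similarity([0, 0], [0, 0])
    # one empty margin: similarity 0 by design decision, not an error
    assert kulczynski_similarity([1, 1], [0, 0]) == 0.0


def test_kulczynski_equals_dice_on_equal_margins():
    from cladecoev import dice_similarity

    rng = np.random.default_rng(1)
    for _ in range(20):
        x = rng.integers(0, 2, size=12)
        y = rng.integers(0, 2, size=12)
        if x.sum() == y.sum() and (x & y).sum() > 0:
            assert kulczynski_similarity(x, y) == pytest.approx(
                dice_similarity(x, y))


def test_group_similarity_hand_computed_table():
    df = pd.DataFrame({"g1": [1, 1, 0, 0], "g2": [1, 1, 0, 0],
                       "g3": [0, 1, 1, 0]})
    sim = group_similarity(GroupEventMatrix(df)).similarity
    assert sim.loc["g1", "g2"] == 1.0
    # g1 vs g3: a=1, b=1, c=1 -> 0.5
    assert sim.loc["g1", "g3"] == 0.5
    assert np.allclose(sim.to_numpy(), sim.to_numpy().T)
    assert np.allclose(np.diag(sim.to_numpy()), 1.0)


def test_zero_event_groups_are_excluded():
    df = pd.DataFrame({"g1": [1, 0], "g2": [1, 1], "dead": [0, 0]})
    sim = group_similarity(GroupEventMatrix(df))
    assert "dead" not in sim.labels
    with pytest.raises(ContractError):
        group_similarity(GroupEventMatrix(pd.DataFrame({"a": [1, 0],
                                                        "dead": [0, 0]})))


def test_single_linkage_nearest_neighbour_order():
    d = pd.DataFrame([[0.0, 0.1, 0.5],
                      [0.1, 0.0, 0.9],
                      [0.5, 0.9, 0.0]],
                     index=list("abc"), columns=list("abc"))
    from cladecoev import SimilarityMatrix

    sm = SimilarityMatrix(1.0 - d)
    den = single_linkage(sm)
    merges = den.merges()
    assert merges[0][0] | merges[0][1] == {"a", "b"}
    assert merges[0][2] == pytest.approx(0.1)
    assert merges[1][2] == pytest.approx(0.5)  # c joins at min(d(a,c), d(b,c))
    heights = den.merge_heights()
    assert (np.diff(heights) >= 0).all()


def test_cophenetic_distance_never_exceeds_input():
    rng = np.random.default_rng(7)
    n = 6
    d = rng.random((n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    labels = [f"g{i}" for i in range(n)]
    from cladecoev import SimilarityMatrix

    sm = SimilarityMatrix(pd.DataFrame(1 - d, index=labels, columns=labels))
    den = single_linkage(sm)
    coph = den.cophenetic().to_numpy()
    assert (coph <= d + 1e-12).all()


def test_items_at_distance_zero_merge_first():
    from cladecoev import SimilarityMatrix

    labels = list("wxyz")
    d = np.full((4, 4), 0.8)
    np.fill_diagonal(d, 0)
    d[0, 1] = d[1, 0] = 0.0
    sm = SimilarityMatrix(pd.DataFrame(1 - d, index=labels, columns=labels))
    first = single_linkage(sm).merges()[0]
    assert first[0] | first[1] == {"w", "x"}
    assert first[2] == 0.0


# --------------------------------------------------------------------------
# ANOSIM
# --------------------------------------------------------------------------

def _distance_frame(d, labels):
    return pd.DataFrame(d, index=labels, columns=labels)


def test_anosim_perfect_separation_gives_r_one():
    labels = list("abcd")
    d = np.array([[0.0, 0.1, 0.9, 0.8],
                  [0.1, 0.0, 0.7, 0.9],
                  [0.9, 0.7, 0.0, 0.2],
                  [0.8, 0.9, 0.2, 0.0]])
    res = anosim(_distance_frame(d, labels),
                 {"a": 1, "b": 1, "c": 2, "d": 2}, seed=0)
    assert res.r == pytest.approx(1.0)
    assert res.exact


def test_anosim_exact_p_matches_full_enumeration():
    """4 items in 2+2 classes: p from the 3 distinct label splits."""
    labels = list("abcd")
    d = np.array([[0.0, 0.1, 0.9, 0.8],
                  [0.1, 0.0, 0.7, 0.9],
                  [0.9, 0.7, 0.0, 0.2],
                  [0.8, 0.9, 0.2, 0.0]])
    factor = {"a": 1, "b": 1, "c": 2, "d": 2}
    res = anosim(_distance_frame(d, labels), factor, seed=0)

    # independent oracle: rank distances once, enumerate the three splits
    from scipy.stats import rankdata

    iu = np.triu_indices(4, 1)
    ranks = rankdata(d[iu])
    pairs = list(zip(*iu))

    def r_stat(assign):
        within = [assign[i] == assign[j] for i, j in pairs]
        rb = ranks[[not w for w in within]].mean()
        rw = ranks[within].mean()
        return (rb - rw) / (4 * 3 / 4)

    splits = [(1, 1, 2, 2), (1, 2, 1, 2), (1, 2, 2, 1)]
    stats = [r_stat(s) for s in splits]
    observed = stats[0]
    expect_p = sum(s >= observed - 1e-12 for s in stats) / 3
    # the package enumerates labelled assignments (6) but the ratio is equal
    assert res.p_value == pytest.approx(expect_p)
    assert res.r == pytest.approx(observed)


def test_anosim_r_invariant_under_monotone_distance_transform():
    rng = np.random.default_rng(4)
    n = 7
    d = rng.random((n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    labels = [f"g{i}" for i in range(n)]
    factor = {l: (0 if i < 3 else 1) for i, l in enumerate(labels)}
    a = anosim(_distance_frame(d, labels), factor, seed=1)
    b = anosim(_distance_frame(np.sqrt(d), labels), factor, seed=1)
    assert a.r == pytest.approx(b.r)
    assert a.p_value == pytest.approx(b.p_value)


def test_anosim_null_centers_near_zero():
    rng = np.random.default_rng(9)
    n = 9
    d = rng.random((n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    labels = [f"g{i}" for i in range(n)]
    rs = []
    for seed in range(30):
        perm = rng.permutation(n)
        factor = {labels[int(i)]: (0 if k < 4 else 1)
                  for k, i in enumerate(perm)}
        rs.append(anosim(_distance_frame(d, labels), factor,
                         seed=seed, exact_cap=10).r)
    assert abs(np.mean(rs)) < 0.15


def test_anosim_agrees_with_reference_implementation():
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import anosim as sk_anosim

    rng = np.random.default_rng(13)
    n = 8
    d = rng.random((n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    labels = [f"g{i}" for i in range(n)]
    grouping = [0, 0, 0, 1, 1, 1, 1, 0]
    factor = dict(zip(labels, grouping))
    mine = anosim(_distance_frame(d, labels), factor, seed=3)
    ref = sk_anosim(DistanceMatrix(d, ids=labels), grouping=grouping,
                    permutations=999)
    assert mine.r == pytest.approx(float(ref["test statistic"]), abs=1e-12)


# --------------------------------------------------------------------------
# NMDS
# --------------------------------------------------------------------------

def test_nmds_embeds_a_triangle_with_negligible_stress():
    labels = list("abc")
    d = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
    res = nmds(_distance_frame(d, labels), dims=2, n_restarts=4, seed=2)
    assert res.stress < 1e-6
    assert res.coordinates.shape == (3, 2)


def test_nmds_dimensionality_contract():
    labels = list("abcde")
    rng = np.random.default_rng(0)
    d = rng.random((5, 5))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    res = nmds(_distance_frame(d, labels), dims=3, n_restarts=2, seed=5)
    assert res.coordinates.shape == (5, 3)
    with pytest.raises(ContractError):
        nmds(_distance_frame(d, labels), dims=5, seed=5)


def test_best_restart_is_no_worse_than_any_restart():
    labels = [f"g{i}" for i in range(6)]
    rng = np.random.default_rng(8)
    d = rng.random((6, 6))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    res = nmds(_distance_frame(d, labels), dims=2, n_restarts=6, seed=3)
    assert res.stress <= min(res.restart_stresses) + 1e-12
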