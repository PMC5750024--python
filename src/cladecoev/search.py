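"""Tree search under the parsimony criterion.

Search operates over unrooted topologies, represented internally as nested
tuples of taxon indices hanging from a fixed "handle" leaf; rooting on the
outgroup is purely presentational and applied when results are packaged.

Three engines share the same vectorised Fitch scorer:

* ``exhaustive_search`` scores every unrooted topology (the oracle; only
  feasible for small taxon counts),
* ``branch_and_bound_search`` is exact implicit enumeration: depth-first
  taxon addition with an admissible lower bound (partial-tree length plus
  one step per state not yet represented among the placed taxa), seeded
  with a greedy-addition upper bound, returning *all* most-parsimonious
  trees,
* ``heuristic_search`` does random-addition greedy insertion followed by
  nearest-neighbour-interchange swapping, deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError
from .fitch import leaf_mask_matrix
from .matrix import CharacterMatrix
from .tree import Node, PhyloTree

_TOL = 1e-9


# --------------------------------------------------------------------------
# Tuple-tree plumbing
# --------------------------------------------------------------------------

def _insertions(t, leaf):
    """All trees obtained by attaching ``leaf`` to one edge of ``t``.

    ``t`` is a nested tuple (or a bare leaf index) hanging from the handle
    leaf; the first yield attaches on the handle edge itself.
    """
    yield (t, leaf)
    if isinstance(t, tuple):
        a, b = t
        for a2 in _insertions(a, leaf):
            yield (a2, b)
        for b2 in _insertions(b, leaf):
            yield (a, b2)


def _all_topologies(n_taxa: int, first: int = 1):
    """Every unrooted binary topology over taxa ``0..n_taxa-1`` exactly once."""

    def rec(k):
        if k == first:
            yield k
            return
        for t in rec(k - 1):
            yield from _insertions(t, k)

    yield from rec(n_taxa - 1)


def _nni_neighbors(t):
    """All nearest-neighbour-interchange rearrangements of a tuple tree."""
    out = []

    def rec(node, rebuild):
        if not isinstance(node, tuple):
            return
        a, b = node
        if isinstance(a, tuple):
            x, y = a
            out.append(rebuild(((x, b), y)))
            out.append(rebuild(((y, b), x)))
        if isinstance(b, tuple):
            x, y = b
            out.append(rebuild(((x, a), y)))
            out.append(rebuild(((y, a), x)))
        rec(a, lambda na: rebuild((na, b)))
        rec(b, lambda nb: rebuild((a, nb)))

    rec(t, lambda x: x)
    return out


def _tuple_leaves(t) -> list:
    if not isinstance(t, tuple):
        return [t]
    return _tuple_leaves(t[0]) + _tuple_leaves(t[1])


def _tuple_splits(t, handle: int, n: int) -> frozenset:
    """Non-trivial splits (as frozensets of the side without ``handle``)."""
    splits = []

    def rec(x):
        if not isinstance(x, tuple):
            return frozenset((x,))
        s = rec(x[0]) | rec(x[1])
        if 2 <= len(s) <= n - 2:
            splits.append(s)
        return s

    rec(t)
    return frozenset(splits)


class _Scorer:
    """Vectorised Fitch scoring of tuple trees over a fixed taxon order."""

    def __init__(self, m: CharacterMatrix):
        self.masks = leaf_mask_matrix(m)
        self.weights = m.weights
        self.n = m.n_taxa

    def steps(self, t, handle: int) -> np.ndarray:
        def down(node):
            if not isinstance(node, tuple):
                return self.masks[node]
            a = down(node[0])
            b = down(node[1])
            inter = a & b
            need = inter == 0
            steps[need] += 1
            return np.where(need, a | b, inter)

        steps = np.zeros(self.masks.shape[1], dtype=np.int64)
        root = down(t)
        inter = root & self.masks[handle]
        steps[inter == 0] += 1
        return steps

    def length(self, t, handle: int) -> float:
        return float(self.weights @ self.steps(t, handle))


def _tuple_to_phylo(t, handle: int, taxa: list, outgroup: str) -> PhyloTree:
    def conv(node) -> Node:
        if not isinstance(node, tuple):
            return Node(label=taxa[node])
        return Node(children=[conv(node[0]), conv(node[1])])

    rooted = PhyloTree(Node(children=[Node(label=taxa[handle]), conv(t)]))
    return rooted.rooted_on(outgroup)


# --------------------------------------------------------------------------
# Results
# --------------------------------------------------------------------------

@dataclass
class SearchResult:
    """All most-parsimonious trees plus bookkeeping for one search."""

    best_length: float
    mp_trees: list
    per_character_lengths: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.mp_trees)


def _package(optima, scorer, handle, taxa, outgroup, diagnostics) -> SearchResult:
    trees, seen = [], set()
    for t in optima:
        pt = _tuple_to_phylo(t, handle, taxa, outgroup)
        key = pt.topology_key()
        if key not in seen:
            seen.add(key)
            trees.append(pt)
    trees.sort(key=lambda pt: pt.newick())
    best = scorer.length(optima[0], handle)
    if np.allclose(scorer.weights, np.round(scorer.weights)):
        best = int(round(best))
    per_char = scorer.steps(optima[0], handle)
    return SearchResult(best, trees, per_char, diagnostics)


def _check_inputs(m: CharacterMatrix, outgroup: str) -> None:
    if m.n_taxa < 3:
        raise ContractError("search requires at least three taxa")
    if outgroup not in m.taxa:
        raise ContractError(f"outgroup {outgroup!r} not among matrix taxa")


# --------------------------------------------------------------------------
# Exhaustive enumeration (the oracle)
# --------------------------------------------------------------------------

def exhaustive_search(m: CharacterMatrix, outgroup: str) -> SearchResult:
    """Score every unrooted topology; exact but factorial in taxon count."""
    _check_inputs(m, outgroup)
    if m.n_taxa > 9:
        raise ContractError("exhaustive enumeration is limited to 9 taxa")
    scorer = _Scorer(m)
    best, optima, visited = np.inf, [], 0
    for t in _all_topologies(m.n_taxa):
        visited += 1
        length = scorer.length(t, 0)
        if length < best - _TOL:
            best, optima = length, [t]
        elif length <= best + _TOL:
            optima.append(t)
    return _package(optima, scorer, 0, m.taxa, outgroup,
                    {"engine": "exhaustive", "topologies_scored": visited})


# --------------------------------------------------------------------------
# Branch and bound
# --------------------------------------------------------------------------

def _addition_order(m: CharacterMatrix) -> list:
    """Taxa ordered by decreasing character conflict (pairwise difference).

    Placing the most divergent taxa first makes partial-tree lengths grow
    quickly, which tightens the bound early.
    """
    codes = m.codes
    n = m.n_taxa
    totals = np.zeros(n)
    for i in range(n):
        both = (codes[i] >= 0) & (codes >= 0)
        totals[i] = ((codes[i] != codes) & both).sum()
    return sorted(range(n), key=lambda i: (-totals[i], i))


def _greedy_addition(scorer: _Scorer, order: list):
    """Stepwise addition: insert each taxon at its best position."""
    t = (order[1], order[2])
    for leaf in order[3:]:
        t = min(_insertions(t, leaf), key=lambda x: scorer.length(x, order[0]))
    return t


def _remaining_state_bound(m: CharacterMatrix, order: list) -> np.ndarray:
    """Admissible per-depth additive bound.

    After the first ``k`` taxa of the addition order are placed, every
    state present only among the remaining taxa still has to arise at
    least once; each such state adds one weighted step.
    """
    codes = m.codes
    single = np.zeros((m.n_taxa, m.n_chars), dtype=np.uint16)
    obs = codes >= 0
    single[obs] = 1 << codes[obs].astype(np.uint16)
    single = single[order]
    n = m.n_taxa
    suffix = np.zeros((n + 1, m.n_chars), dtype=np.uint16)
    for k in range(n - 1, -1, -1):
        suffix[k] = suffix[k + 1] | single[k]
    prefix = np.zeros(m.n_chars, dtype=np.uint16)
    bound = np.zeros(n + 1)
    popcount = np.array([bin(v).count("1") for v in range(1 << 10)])
    for k in range(n + 1):
        new = suffix[k] & ~prefix
        bound[k] = float(m.weights @ popcount[new])
        if k < n:
            prefix = prefix | single[k]
    return bound


def branch_and_bound_search(m: CharacterMatrix, outgroup: str,
                            max_taxa: int = 25) -> SearchResult:
    """Exact implicit enumeration of all most-parsimonious trees."""
    _check_inputs(m, outgroup)
    if m.n_taxa > max_taxa:
        raise ContractError(
            f"{m.n_taxa} taxa exceed the exact-search ceiling ({max_taxa}); "
            "use heuristic_search instead")
    scorer = _Scorer(m)
    order = _addition_order(m)
    handle = order[0]
    n = m.n_taxa
    bound_extra = _remaining_state_bound(m, order)

    greedy = _greedy_addition(scorer, order)
    best = scorer.length(greedy, handle)
    optima: list = []
    visited = 0

    start = (order[1], order[2])

    def dfs(t, depth):
        # depth = number of taxa placed
        nonlocal best, optima, visited
        leaf = order[depth]
        children = []
        for cand in _insertions(t, leaf):
            visited += 1
            length = scorer.length(cand, handle)
            if length + bound_extra[depth + 1] <= best + _TOL:
                children.append((length, cand))
        children.sort(key=lambda lc: lc[0])
        for length, cand in children:
            if depth + 1 == n:
                if length < best - _TOL:
                    best = length
                    optima = [cand]
                elif length <= best + _TOL:
                    optima.append(cand)
            else:
                if length + bound_extra[depth + 1] <= best + _TOL:
                    dfs(cand, depth + 1)

    if n == 3:
        optima = [start]
        best = scorer.length(start, handle)
    else:
        dfs(start, 3)
        # prune optima that slipped in before later improvements
        optima = [t for t in optima
                  if scorer.length(t, handle) <= best + _TOL]
    return _package(optima, scorer, handle, m.taxa, outgroup,
                    {"engine": "branch_and_bound", "nodes_visited": visited,
                     "upper_bound_used": float(best)})


def constrained_best_length(m: CharacterMatrix, outgroup: str,
                            forbidden_clade: frozenset,
                            cap: float = np.inf,
                            reference_length: float = 0.0):
    """Best length among trees *not* containing a given split.

    The split is given as a set of taxon labels (the ingroup side).  Used
    for Bremer decay: the search prunes once a branch cannot beat either
    the best constrained tree found so far or ``reference_length + cap``.
    Returns ``None`` if every tree within the cap contains the split.
    """
    _check_inputs(m, outgroup)
    scorer = _Scorer(m)
    order = _addition_order(m)
    handle = order[0]
    n = m.n_taxa
    bound_extra = _remaining_state_bound(m, order)
    label_to_idx = m.taxon_index()
    side = frozenset(label_to_idx[t] for t in forbidden_clade)
    if handle in side:
        side = frozenset(range(n)) - side

    best = reference_length + cap  # prune threshold; +cap trees still count
    found = [None]
    visited = 0

    start = (order[1], order[2])

    def complete_ok(t) -> bool:
        return side not in _tuple_splits(t, handle, n)

    def dfs(t, depth):
        nonlocal best, visited
        leaf = order[depth]
        children = []
        for cand in _insertions(t, leaf):
            visited += 1
            length = scorer.length(cand, handle)
            if length + bound_extra[depth + 1] <= best + _TOL:
                children.append((length, cand))
        children.sort(key=lambda lc: lc[0])
        for length, cand in children:
            if depth + 1 == n:
                if length <= best + _TOL and complete_ok(cand):
                    if length < best - _TOL or found[0] is None:
                        best = length
                        found[0] = cand
            else:
                if length + bound_extra[depth + 1] <= best + _TOL:
                    dfs(cand, depth + 1)

    if n == 3:
        if complete_ok(start):
            found[0] = start
            best = scorer.length(start, handle)
    else:
        dfs(start, 3)
    if found[0] is None:
        return None
    return best


def suboptimal_trees(m: CharacterMatrix, outgroup: str, best_length: float,
                     max_extra: int = 8, max_trees: int = 10000):
    """All trees within ``max_extra`` steps of ``best_length`` (capped).

    Compatibility mode mirroring the save-suboptimal-trees protocol used by
    heuristic Bremer implementations; exact here because enumeration is
    branch-and-bound with the relaxed bound.
    """
    _check_inputs(m, outgroup)
    scorer = _Scorer(m)
    order = _addition_order(m)
    handle = order[0]
    n = m.n_taxa
    bound_extra = _remaining_state_bound(m, order)
    limit = best_length + max_extra
    kept: list = []

    start = (order[1], order[2])

    def dfs(t, depth):
        leaf = order[depth]
        for cand in _insertions(t, leaf):
            length = scorer.length(cand, handle)
            if length + bound_extra[depth + 1] > limit + _TOL:
                continue
            if depth + 1 == n:
                if len(kept) < max_trees:
                    kept.append((length, cand))
            else:
                dfs(cand, depth + 1)

    if n == 3:
        kept.append((scorer.length(start, handle), start))
    else:
        dfs(start, 3)
    return [(length, _tuple_to_phylo(t, handle, m.taxa, outgroup))
            for length, t in kept]


# --------------------------------------------------------------------------
# Heuristic search
# --------------------------------------------------------------------------

def heuristic_search(m: CharacterMatrix, outgroup: str, n_starts: int = 10,
                     seed: int = None, nni: bool = True) -> SearchResult:
    """Random-addition greedy insertion plus NNI branch swapping.

    Never reports a length below the exact optimum (it only scores real
    trees); with enough starts on clean data it finds the optimum.
    Deterministic for a given seed.
    """
    _check_inputs(m, outgroup)
    if seed is None:
        raise ContractError("heuristic_search requires an explicit seed")
    rng = np.random.default_rng(seed)
    scorer = _Scorer(m)
    n = m.n_taxa
    best = np.inf
    optima: list = []
    keys: set = set()

    for _ in range(max(1, n_starts)):
        order = [int(i) for i in rng.permutation(n)]
        handle = order[0]
        t = (order[1], order[2])
        for leaf in order[3:]:
            t = min(_insertions(t, leaf), key=lambda x: scorer.length(x, handle))
        length = scorer.length(t, handle)
        if nni and n > 4:
            improved = True
            while improved:
                improved = False
                for cand in _nni_neighbors(t):
                    cl = scorer.length(cand, handle)
                    if cl < length - _TOL:
                        t, length = cand, cl
                        improved = True
                        break
        if length < best - _TOL:
            best = length
            optima, keys = [], set()
        if length <= best + _TOL:
            pt = _tuple_to_phylo(t, handle, m.taxa, outgroup)
            key = pt.topology_key()
            if key not in keys:
                keys.add(key)
                optima.append(pt)

    optima.sort(key=lambda pt: pt.newick())
    if np.allclose(m.weights, np.round(m.weights)):
        best = int(round(best))
    _, per_char = _phylo_steps(optima[0], m, scorer)
    return SearchResult(best, optima, per_char,
                        {"engine": "heuristic", "n_starts": n_starts,
                         "seed": seed})


def _phylo_steps(pt: PhyloTree, m: CharacterMatrix, scorer: _Scorer):
    from .fitch import fitch_length

    return fitch_length(pt, m)
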