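"""Fitch parsimony scoring and ensemble homoplasy indices.

Characters are unordered (non-additive) and weighted; a state change
between any two states costs one step times the character weight.  Missing
and inapplicable codings contribute the full universe of states observed in
that character, so they can never add steps.

States are packed as bitmasks (state s -> bit s) and the Fitch downpass is
vectorised across all characters at once, which keeps tree scoring cheap
inside the branch-and-bound search.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .errors import ContractError, UndefinedIndexError
from .matrix import INAPPLICABLE, MISSING, CharacterMatrix
from .tree import PhyloTree

N_STATES = 10


def leaf_mask_matrix(m: CharacterMatrix) -> np.ndarray:
    """(n_taxa, n_chars) uint16 state bitmasks for the Fitch downpass.

    Missing/inapplicable cells receive the union of the states observed in
    their column (the full per-character state universe); a column with no
    observed state at all degenerates to the single state 0.
    """
    codes = m.codes
    masks = np.zeros(codes.shape, dtype=np.uint16)
    observed = codes >= 0
    masks[observed] = (1 << codes[observed].astype(np.uint16))
    universe = np.bitwise_or.reduce(masks, axis=0)
    universe[universe == 0] = 1
    blank = ~observed
    masks[blank] = np.broadcast_to(universe, codes.shape)[blank]
    return masks


def _postorder_steps(root, leaf_masks: np.ndarray, leaf_index: dict) -> np.ndarray:
    """Per-character Fitch steps for a rooted tree of ``tree.Node`` objects."""
    n_chars = leaf_masks.shape[1]
    steps = np.zeros(n_chars, dtype=np.int64)

    def down(node) -> np.ndarray:
        if node.is_leaf:
            return leaf_masks[leaf_index[node.label]]
        acc = down(node.children[0])
        for child in node.children[1:]:
            b = down(child)
            inter = acc & b
            union_needed = inter == 0
            steps[union_needed] += 1
            acc = np.where(union_needed, acc | b, inter)
        return acc

    down(root)
    return steps


def fitch_length(t: PhyloTree, m: CharacterMatrix):
    """Total weighted parsimony length of ``t`` on ``m``.

    Returns ``(total, per_character)`` where ``per_character`` is the
    unweighted step vector.  The score is a function of the unrooted
    topology, so any rooting of the same tree gives the same value.
    """
    if t.taxa != frozenset(m.taxa):
        extra = sorted(t.taxa - frozenset(m.taxa))[:3]
        miss = sorted(frozenset(m.taxa) - t.taxa)[:3]
        raise ContractError(
            f"tree/matrix taxon mismatch (tree-only: {extra}, matrix-only: {miss})")
    masks = leaf_mask_matrix(m)
    steps = _postorder_steps(t.root, masks, m.taxon_index())
    total = float(np.dot(m.weights, steps))
    if np.allclose(m.weights, np.round(m.weights)):
        total = int(round(total))
    return total, steps


def min_steps(column: np.ndarray) -> int:
    """Fewest steps the character can need on any tree: (observed states) - 1."""
    column = np.asarray(column)
    if column.size == 0:
        raise ContractError("empty character column")
    k = np.unique(column[column >= 0]).size
    return max(k - 1, 0)


def max_steps(column: np.ndarray) -> int:
    """Most steps the character can need on any tree.

    For an unordered character this is reached on the worst tree and equals
    (number of non-missing codings) minus (count of the most frequent
    state): every coding outside the majority state then changes
    independently.
    """
    column = np.asarray(column)
    if column.size == 0:
        raise ContractError("empty character column")
    observed = column[column >= 0]
    if observed.size == 0:
        return 0
    _, counts = np.unique(observed, return_counts=True)
    return int(observed.size - counts.max())


def is_informative(column: np.ndarray) -> bool:
    """Parsimony-informative: at least two states each seen in >= 2 taxa."""
    observed = np.asarray(column)
    observed = observed[observed >= 0]
    if observed.size == 0:
        return False
    _, counts = np.unique(observed, return_counts=True)
    return int((counts >= 2).sum()) >= 2


@dataclass(frozen=True)
class HomoplasyIndices:
    """Ensemble consistency and retention indices with percent renderings."""

    ci: Fraction
    ri: Fraction

    @staticmethod
    def _pct(x: Fraction) -> int:
        return int(100 * x + Fraction(1, 2))  # round half up

    @property
    def ci_percent(self) -> int:
        return self._pct(self.ci)

    @property
    def ri_percent(self) -> int:
        return self._pct(self.ri)


def ensemble_indices(t: PhyloTree, m: CharacterMatrix,
                     exclude_uninformative: bool = False) -> HomoplasyIndices:
    """Ensemble CI = sum(m)/sum(s) and RI = (sum(g)-sum(s))/(sum(g)-sum(m)).

    ``m``, ``s`` and ``g`` are the per-character minimum, observed and
    maximum step counts.  ``exclude_uninformative`` drops
    parsimony-uninformative characters from the sums (conventions differ
    between programs; both renderings are available).
    """
    _, steps = fitch_length(t, m)
    keep = np.ones(m.n_chars, dtype=bool)
    if exclude_uninformative:
        keep = np.array([is_informative(m.codes[:, j]) for j in range(m.n_chars)])
    mins = np.array([min_steps(m.codes[:, j]) for j in range(m.n_chars)])
    maxs = np.array([max_steps(m.codes[:, j]) for j in range(m.n_chars)])
    sm = int(mins[keep].sum())
    ss = int(steps[keep].sum())
    sg = int(maxs[keep].sum())
    if ss == 0:
        raise UndefinedIndexError("no variable characters: CI/RI undefined")
    ci = Fraction(sm, ss)
    if sg == sm:
        # every character at its minimum on every tree; conventionally RI = 1
        ri = Fraction(1)
    else:
        ri = Fraction(sg - ss, sg - sm)
    return HomoplasyIndices(ci=ci, ri=ri)
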