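"""Clade stability: bootstrap percentages, Bremer decay, consensus trees.

A clade is identified by its set of ingroup taxon labels (the side of the
bipartition not containing the outgroup).  The joint significance rule used
throughout is the conjunction "Bremer decay >= 3 AND bootstrap >= 80%",
with both thresholds inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .matrix import CharacterMatrix
from .search import (SearchResult, branch_and_bound_search,
                     constrained_best_length, heuristic_search)
from .tree import PhyloTree, build_tree_from_clades

log = logging.getLogger(__name__)

BREMER_MIN = 3
BOOTSTRAP_MIN = 80.0


def _tree_clades(t: PhyloTree, outgroup: str) -> set:
    """Non-trivial clades of a tree rooted on the outgroup."""
    rooted = t.rooted_on(outgroup)
    n = len(rooted.taxa)
    return {c for c in rooted.clades()
            if outgroup not in c and 2 <= len(c) <= n - 2}


def consensus(trees: list, rule: str = "strict", cutoff: float = 0.5) -> PhyloTree:
    """Strict or majority-rule consensus of rooted trees.

    ``strict`` keeps clades present in every tree; ``majority`` keeps
    clades present in more than ``cutoff`` of the trees.  The result may be
    multifurcating.
    """
    if not trees:
        raise ContractError("consensus of an empty tree list")
    taxa = trees[0].taxa
    if any(t.taxa != taxa for t in trees):
        raise ContractError("consensus requires identical taxon sets")
    if rule not in ("strict", "majority"):
        raise ValueError(f"unknown consensus rule {rule!r}")
    counts: dict = {}
    for t in trees:
        for c in set(t.clades()):
            counts[c] = counts.get(c, 0) + 1
    n = len(trees)
    if rule == "strict":
        keep = [c for c, k in counts.items() if k == n]
    else:
        keep = [c for c, k in counts.items() if k > cutoff * n]
    return build_tree_from_clades(taxa, keep)


def bootstrap_support(m: CharacterMatrix, outgroup: str, n_reps: int,
                      seed: int, search: str = "heuristic",
                      n_starts: int = 2) -> dict:
    """Nonparametric bootstrap: resample characters, search, count clades.

    Each replicate resamples the matrix columns with replacement to the
    original character count and contributes its most-parsimonious trees'
    clades with weight 1/k when k optima are found.  Returns clade ->
    frequency in percent.  Failed replicates are dropped and counted in
    the log.
    """
    if n_reps < 1:
        raise ContractError("n_reps must be >= 1")
    if search not in ("heuristic", "exact"):
        raise ValueError(f"unknown search mode {search!r}")
    rng = np.random.default_rng(seed)
    freqs: dict = {}
    completed = 0
    for _ in range(n_reps):
        cols = rng.integers(0, m.n_chars, size=m.n_chars)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        rep = m.select_columns(cols)
        try:
            if search == "exact":
                res = branch_and_bound_search(rep, outgroup)
            else:
                res = heuristic_search(rep, outgroup, n_starts=n_starts,
                                       seed=rep_seed)
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("bootstrap replicate failed and was dropped: %s", exc)
            continue
        completed += 1
        w = 1.0 / len(res.mp_trees)
        for t in res.mp_trees:
            for clade in _tree_clades(t, outgroup):
                freqs[clade] = freqs.get(clade, 0.0) + w
    if completed == 0:
        raise ContractError("all bootstrap replicates failed")
    if completed < n_reps:
        log.warning("bootstrap: %d of %d replicates dropped",
                    n_reps - completed, n_reps)
    return {c: 100.0 * v / completed for c, v in freqs.items()}


def bremer_support(m: CharacterMatrix, outgroup: str, best: SearchResult,
                   cap: int = 8) -> dict:
    """Exact Bremer decay per clade of the strict consensus of MP trees.

    decay(clade) = (best length among trees lacking the clade) - best
    length overall, found by constrained branch and bound.  Values above
    ``cap`` are reported as ``cap`` with the ``capped`` convention of
    :func:`render_bremer` ("greater than or equal").  Clades absent from
    the strict consensus have decay 0 by definition.
    """
    rooted = [t.rooted_on(outgroup) for t in best.mp_trees]
    cons = consensus(rooted, rule="strict")
    n = len(cons.taxa)
    clades = {c for c in cons.clades()
              if outgroup not in c and 2 <= len(c) <= n - 2}
    out: dict = {}
    for clade in sorted(clades, key=lambda c: (len(c), sorted(c))):
        constrained = constrained_best_length(
            m, outgroup, clade, cap=cap + 0.5,
            reference_length=float(best.best_length))
        if constrained is None:
            out[clade] = (cap, True)  # decay >= cap (capped)
        else:
            decay = int(round(constrained - best.best_length))
            out[clade] = (min(decay, cap), decay > cap)
    return out


def render_bremer(value) -> str:
    decay, capped = value
    if decay is None or (isinstance(decay, float) and np.isnan(decay)):
        return "-"
    decay = int(decay)
    return f">={decay}" if capped else str(decay)


@dataclass
class SupportTable:
    """Per-clade bootstrap and Bremer values with the joint significance flag."""

    table: pd.DataFrame  # columns: clade, bootstrap_pct, bremer, capped, significant

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df["clade"] = df["clade"].map(lambda c: ",".join(sorted(c)))
        df["bremer"] = [render_bremer((b, c)) for b, c
                        in zip(self.table["bremer"], self.table["capped"])]
        df.drop(columns=["capped"]).to_csv(path, sep="\t", index=False)

    def significant_clades(self) -> list:
        return list(self.table.loc[self.table["significant"], "clade"])


def flag_significant(boot: dict, bremer: dict,
                     bootstrap_min: float = BOOTSTRAP_MIN,
                     bremer_min: int = BREMER_MIN) -> SupportTable:
    """Join the two support tables and apply the conjunction rule.

    A clade present in only one table is retained with the missing value
    as NaN and flagged non-significant (with a logged warning).
    """
    clades = sorted(set(boot) | set(bremer), key=lambda c: (len(c), sorted(c)))
    missing = sum(1 for c in clades if c not in boot or c not in bremer)
    if missing:
        log.warning("%d of %d clades present in only one support table "
                    "(flagged non-significant)", missing, len(clades))
    rows = []
    for clade in clades:
        b = boot.get(clade)
        d = bremer.get(clade)
        decay, capped = d if d is not None else (np.nan, False)
        significant = (b is not None and d is not None
                       and b >= bootstrap_min and decay >= bremer_min)
        rows.append({"clade": clade,
                     "bootstrap_pct": np.nan if b is None else b,
                     "bremer": decay, "capped": capped,
                     "significant": bool(significant)})
    return SupportTable(pd.DataFrame(rows))


def annotate_tree(t: PhyloTree, outgroup: str, boot: dict, bremer: dict) -> str:
    """Newick with "bootstrap/bremer" labels on internal nodes."""
    rooted = t.rooted_on(outgroup)

    def fmt(node) -> str:
        if node.is_leaf:
            return node.label
        inner = "(" + ",".join(fmt(c) for c in node.children) + ")"
        leafset = frozenset(_leaves(node))
        label = ""
        if leafset in boot or leafset in bremer:
            b = boot.get(leafset)
            d = bremer.get(leafset)
            btxt = "-" if b is None else f"{b:.0f}"
            dtxt = "-" if d is None else render_bremer(d)
            label = f"{btxt}/{dtxt}"
        return inner + label

    def _leaves(node):
        if node.is_leaf:
            return [node.label]
        return [x for c in node.children for x in _leaves(c)]

    return fmt(rooted.root) + ";"
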