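"""Ancestral-state reconstruction and per-branch character-change events.

Every branch of the total-evidence tree is treated as a potential
"evolutionary event": a character changing state along it.  Reconstruction
is minimum-change (unit-cost Sankoff tables, equivalent to Fitch for
unordered characters) with three mapping conventions:

* ``unambiguous`` - emit a change on a branch only when the minimal-state
  sets of its two ends are disjoint, i.e. the change occurs in every
  most-parsimonious reconstruction (the reliable-synapomorphy display);
* ``acctran`` / ``deltran`` - resolve ambiguity by preferring, whenever a
  state choice is cost-neutral, the change on the current (rootward) branch
  or on a later branch respectively; both are exact minimum reconstructions
  so per-character event counts equal the character's Fitch length.

Events aggregate into a nodes x anatomical-groups matrix, binarised by
default ("did any character of this group change on this branch?"), which
is the input to the coevolution statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .matrix import CharacterGroupMap, CharacterMatrix
from .tree import PhyloTree

log = logging.getLogger(__name__)

_INF = 10**6


@dataclass(frozen=True)
class ChangeEvent:
    """One character changing state on one branch (identified by its clade)."""

    clade: frozenset  # leaves below the branch
    char_id: int
    from_states: frozenset
    to_states: frozenset
    ambiguous: bool


class _FlatTree:
    """Arrays-of-nodes view of a rooted binary tree for the DP passes."""

    def __init__(self, t: PhyloTree):
        self.nodes = []  # (label_or_None, [child indices], clade frozenset)
        self.parent = []
        self.root = self._build(t.root)

    def _build(self, node) -> int:
        kids = [self._build(c) for c in node.children]
        if node.is_leaf:
            clade = frozenset([node.label])
        else:
            clade = frozenset().union(*(self.nodes[k][2] for k in kids))
        self.nodes.append((node.label, kids, clade))
        self.parent.append(-1)
        idx = len(self.nodes) - 1
        for k in kids:
            self.parent[k] = idx
        return idx

    def postorder(self):
        return range(len(self.nodes))  # children are built before parents

    def preorder(self):
        return range(len(self.nodes) - 1, -1, -1)


def _column_tables(flat: _FlatTree, column: np.ndarray, taxon_index: dict):
    """Down-costs, up-costs and minimal-state (MPR) sets for one character.

    Returns ``(states, down, up, opt)`` where ``down[v]`` / ``up[v]`` are
    cost vectors over the observed-state list ``states`` and ``opt`` is the
    character's minimum length.  ``None`` when fewer than two states are
    observed (no change anywhere).
    """
    observed = sorted(set(int(s) for s in column if s >= 0))
    if len(observed) < 2:
        return None
    k = len(observed)
    idx_of = {s: i for i, s in enumerate(observed)}
    nn = len(flat.nodes)
    down = np.zeros((nn, k))
    cheap = np.zeros((nn, k))
    for v in flat.postorder():
        label, kids, _ = flat.nodes[v]
        if not kids:
            code = int(column[taxon_index[label]])
            row = np.full(k, float(_INF))
            if code >= 0:
                row[idx_of[code]] = 0.0
            else:
                row[:] = 0.0  # missing/inapplicable: any state, free
            down[v] = row
        else:
            down[v] = sum(cheap[c] for c in kids)
        cheap[v] = np.minimum(down[v], down[v].min() + 1.0)
    up = np.zeros((nn, k))
    for v in flat.preorder():
        _, kids, _ = flat.nodes[v]
        for c in kids:
            r = up[v] + sum(cheap[o] for o in kids if o != c)
            up[c] = np.minimum(r, r.min() + 1.0)
    opt = float((down[flat.root] + up[flat.root]).min())
    return observed, down, up, opt


def _mpr_sets(states, down, up, opt):
    total = down + up
    return [frozenset(states[i] for i in np.nonzero(row <= opt + 1e-9)[0])
            for row in total]


def fitch_ancestral_sets(t: PhyloTree, column: np.ndarray,
                         taxa: list) -> dict:
    """Downpass and final (uppass) state sets per node of a rooted tree.

    ``column`` is one character's codes aligned with ``taxa``.  Keys are
    node clades (leaf-label frozensets, singletons included); values are
    ``{"down": set, "final": set}``.  Leaves with missing codings carry the
    character's full observed-state universe.
    """
    if not t.is_binary():
        raise ContractError("ancestral reconstruction requires a binary tree")
    flat = _FlatTree(t)
    tix = {lab: i for i, lab in enumerate(taxa)}
    tables = _column_tables(flat, np.asarray(column), tix)
    out = {}
    if tables is None:
        observed = sorted(set(int(s) for s in column if s >= 0)) or [0]
        sset = frozenset(observed)
        for _, _, clade in flat.nodes:
            out[clade] = {"down": sset, "final": sset}
        return out
    states, down, up, opt = tables
    finals = _mpr_sets(states, down, up, opt)
    for v, (_, _, clade) in enumerate(flat.nodes):
        dmin = down[v].min()
        dset = frozenset(states[i] for i in np.nonzero(down[v] <= dmin + 1e-9)[0])
        out[clade] = {"down": dset, "final": finals[v]}
    return out


def _assign(flat: _FlatTree, states, down, mode: str) -> list:
    """One minimum reconstruction as a per-node state assignment."""
    nn = len(flat.nodes)
    assign = [None] * nn
    for v in flat.preorder():
        p = flat.parent[v]
        if p == -1:
            cands = np.nonzero(down[v] <= down[v].min() + 1e-9)[0]
            assign[v] = states[int(cands[0])]
            continue
        ps = assign[p]
        pi = states.index(ps)
        cost = down[v] + 1.0
        cost[pi] = down[v][pi]  # staying put costs no step on this edge
        cands = [states[int(i)] for i in np.nonzero(cost <= cost.min() + 1e-9)[0]]
        if mode == "acctran":
            non_parent = [s for s in cands if s != ps]
            assign[v] = non_parent[0] if non_parent else cands[0]
        else:  # deltran
            assign[v] = ps if ps in cands else cands[0]
    return assign


def map_changes(t: PhyloTree, m: CharacterMatrix, mode: str = "unambiguous",
                include_terminals: bool = True) -> list:
    """Character-change events on every branch of a rooted binary tree."""
    if mode not in ("unambiguous", "acctran", "deltran"):
        raise ValueError(f"unknown mapping mode {mode!r}")
    if not t.is_binary():
        raise ContractError("map_changes requires a fully resolved binary tree")
    if t.taxa != frozenset(m.taxa):
        raise ContractError("tree and matrix taxa differ")
    flat = _FlatTree(t)
    tix = m.taxon_index()
    events: list = []
    for j in range(m.n_chars):
        tables = _column_tables(flat, m.codes[:, j], tix)
        if tables is None:
            continue
        states, down, up, opt = tables
        finals = _mpr_sets(states, down, up, opt)
        char_id = int(m.char_ids[j])
        if mode == "unambiguous":
            for v, (_, _, clade) in enumerate(flat.nodes):
                p = flat.parent[v]
                if p == -1 or (len(clade) == 1 and not include_terminals):
                    continue
                if not (finals[p] & finals[v]):
                    events.append(ChangeEvent(clade, char_id,
                                              finals[p], finals[v], False))
        else:
            assign = _assign(flat, states, down, mode)
            for v, (_, _, clade) in enumerate(flat.nodes):
                p = flat.parent[v]
                if p == -1 or (len(clade) == 1 and not include_terminals):
                    continue
                if assign[v] != assign[p]:
                    ambiguous = bool(finals[p] & finals[v])
                    events.append(ChangeEvent(
                        clade, char_id, frozenset([assign[p]]),
                        frozenset([assign[v]]), ambiguous))
    return events


def internal_branches(t: PhyloTree, include_terminals: bool = True) -> list:
    """Clades identifying every branch of the tree (root excluded)."""
    flat = _FlatTree(t)
    out = []
    for v, (_, _, clade) in enumerate(flat.nodes):
        if flat.parent[v] == -1:
            continue
        if len(clade) == 1 and not include_terminals:
            continue
        out.append(clade)
    return out


def clade_label(clade: frozenset) -> str:
    return ",".join(sorted(clade))


@dataclass
class GroupEventMatrix:
    """Branches x anatomical-groups matrix of (synchronous) change events."""

    df: pd.DataFrame  # index: clade labels; columns: group labels

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="node")

    def group_vector(self, group_label: str) -> np.ndarray:
        return self.df[group_label].to_numpy()


def group_event_matrix(events: list, gmap: CharacterGroupMap,
                       nodes: list = None,
                       binarize: bool = True) -> GroupEventMatrix:
    """Aggregate change events by (branch, anatomical group).

    ``nodes`` fixes the row set (so branches with no events appear as zero
    rows); by default rows are the branches seen in ``events``.  Events on
    ungrouped characters are excluded with a logged count.
    """
    if nodes is None:
        nodes = sorted({e.clade for e in events}, key=clade_label)
    group_labels = [gmap.groups[g].label for g in sorted(gmap.groups)]
    index = [clade_label(c) for c in nodes]
    counts = pd.DataFrame(0, index=index, columns=group_labels)
    row_of = {c: clade_label(c) for c in nodes}
    skipped = 0
    for e in events:
        gid = gmap.group_of(e.char_id)
        if gid is None:
            skipped += 1
            continue
        if e.clade not in row_of:
            continue
        counts.loc[row_of[e.clade], gmap.groups[gid].label] += 1
    if skipped:
        log.warning("group_event_matrix: %d events on ungrouped characters "
                    "excluded", skipped)
    if binarize:
        counts = (counts > 0).astype(int)
    return GroupEventMatrix(counts)
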