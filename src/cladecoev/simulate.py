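"""Synthetic trees and character matrices with controllable signal.

The generator emulates the statistical regime of a small morphological
study of copulatory structures: 17-21 terminal taxa (one outgroup), about
75 mostly binary unordered characters organised into anatomical groups,
very low homoplasy (ensemble CI in the high nineties), and - optionally -
"coupled" groups whose characters change on a shared pool of internal
branches, producing the co-change structure the coevolution statistics are
designed to detect.

Character placement samples branches directly instead of running a
clock-like Markov process: the analyses are topology-only, and direct
placement gives exact control over the consistency index and the coupling.
All randomness flows from the single seed in the configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, ValidationError
from .matrix import CharacterGroup, CharacterGroupMap, CharacterMatrix
from .tree import Node, PhyloTree

DEFAULT_GROUP_SIZES = (9, 16, 14, 9, 2, 6, 8, 10)  # 74 grouped + 1 free = 75
DEFAULT_GROUP_LABELS = ("S6", "AS7", "PS7", "S8", "PI", "LA", "PM", "PE")


# --------------------------------------------------------------------------
# Random trees
# --------------------------------------------------------------------------

def random_tree(n_taxa: int, seed: int, labels: list = None) -> PhyloTree:
    """Uniform random rooted binary labelled topology.

    Built by sequential attachment: taxon k may attach to any of the
    2k - 1 branches of the current rooted tree (including the root stem),
    each with equal probability, which yields the uniform distribution
    over the (2n - 3)!! rooted labelled shapes.
    """
    if n_taxa < 3:
        raise ContractError("random_tree requires at least 3 taxa")
    if labels is None:
        labels = [f"t{i + 1:02d}" for i in range(n_taxa)]
    if len(labels) != n_taxa or len(set(labels)) != n_taxa:
        raise ContractError("labels must be unique and match n_taxa")
    rng = np.random.default_rng(seed)
    tree = 0  # nested tuples over taxon indices; int = leaf

    def attach_positions(t):
        yield "stem"
        if isinstance(t, tuple):
            yield from (("a", p) for p in attach_positions(t[0]))
            yield from (("b", p) for p in attach_positions(t[1]))

    def attach(t, pos, leaf):
        if pos == "stem":
            return (t, leaf)
        side, sub = pos
        a, b = t
        if side == "a":
            return (attach(a, sub, leaf), b)
        return (a, attach(b, sub, leaf))

    for k in range(1, n_taxa):
        positions = list(attach_positions(tree))
        pos = positions[int(rng.integers(0, len(positions)))]
        tree = attach(tree, pos, k)

    def conv(t) -> Node:
        if isinstance(t, int):
            return Node(label=labels[t])
        return Node(children=[conv(t[0]), conv(t[1])])

    return PhyloTree(conv(tree))


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic matrix generator.

    ``homoplasy`` is the expected number of extra (convergent) changes per
    character; 0 gives a perfect phylogeny (CI = 1 on the generating
    tree).  ``coupled_groups`` lists (group-index tuple, kappa) pairs:
    with probability kappa a character of a coupled group draws its change
    branch from the group set's shared pool, so kappa = 1 makes the
    coupled groups' branch-event vectors identical.
    """

    seed: int
    n_taxa: int = 17
    n_chars: int = 75
    n_states: int = 2
    homoplasy: float = 0.04
    group_sizes: tuple = None  # None: published layout when it fits
    group_labels: tuple = DEFAULT_GROUP_LABELS
    coupled_groups: tuple = ()  # ((group_idx, ...), kappa) pairs, 0-based
    pool_size: int = None  # branches per coupling pool
    missing_rate: float = 0.0
    outgroup: str = "OUT"

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        if self.group_sizes is None:
            fits = sum(DEFAULT_GROUP_SIZES) <= self.n_chars
            self.group_sizes = DEFAULT_GROUP_SIZES if fits else ()
        if self.group_sizes and sum(self.group_sizes) > self.n_chars:
            raise ValidationError("group sizes exceed n_chars")
        for groups, kappa in self.coupled_groups:
            if not 0.0 <= kappa <= 1.0:
                raise ValidationError("kappa must be in [0, 1]")
            for g in groups:
                if not 0 <= g < len(self.group_sizes):
                    raise ValidationError(f"unknown group index {g}")
        if self.homoplasy < 0:
            raise ValidationError("homoplasy must be >= 0")
        if self.n_states < 2:
            raise ValidationError("characters need at least two states")

    def taxon_labels(self) -> list:
        return [self.outgroup] + [f"G{i:02d}" for i in range(1, self.n_taxa)]

    def group_map(self) -> CharacterGroupMap:
        groups = {}
        start = 1
        for i, (size, label) in enumerate(zip(self.group_sizes,
                                              self.group_labels), start=1):
            groups[i] = CharacterGroup(i, label, ((start, start + size - 1),))
            start += size
        n_thely = 4 if len(self.group_sizes) >= 8 else len(self.group_sizes) // 2
        partitions = {"thelycum": list(range(1, n_thely + 1)),
                      "petasma": list(range(n_thely + 1,
                                            len(self.group_sizes) + 1))}
        return CharacterGroupMap(groups, partitions)


# --------------------------------------------------------------------------
# Matrix simulation
# --------------------------------------------------------------------------

@dataclass
class TruthLog:
    """What the generator actually did, for parameter-recovery tests."""

    tree: PhyloTree
    events: dict = field(default_factory=dict)  # char_id -> [(clade, from, to)]

    def change_clades(self, char_id: int) -> list:
        return [c for c, _, _ in self.events[char_id]]


def _branch_clades(t: PhyloTree):
    """(internal branch clades, terminal branch clades) of a rooted tree."""
    internal, terminal = [], []
    n = len(t.taxa)

    def walk(node) -> frozenset:
        if node.is_leaf:
            s = frozenset([node.label])
            terminal.append(s)
            return s
        s = frozenset().union(*(walk(c) for c in node.children))
        if len(s) < n:
            internal.append(s)
        return s

    walk(t.root)
    return internal, terminal


def simulate_matrix(t: PhyloTree, cfg: SimulationConfig, rng=None):
    """Generate a character matrix on ``t`` plus its truth log.

    Each character receives one primary change branch (perfect phylogeny
    when ``homoplasy`` is 0); Poisson-distributed extra changes add
    homoplasy.  Characters of coupled groups draw their primary branch
    from a shared per-coupling pool of internal branches.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    taxa = t.leaf_labels()
    if len(taxa) != cfg.n_taxa:
        raise ContractError("tree size does not match configuration")
    internal, terminal = _branch_clades(t)
    all_branches = internal + terminal
    if cfg.n_chars < len(internal):
        warnings.warn("fewer characters than internal branches: the "
                      "generating tree may not be identifiable")

    # group membership per character (0-based char index -> group index)
    group_of = {}
    start = 0
    for gi, size in enumerate(cfg.group_sizes):
        for j in range(start, start + size):
            group_of[j] = gi
        start += size

    # coupling pools: one branch pool per coupled set, shared by its groups;
    # pools of different coupling sets are disjoint so the designed blocks
    # stay distinguishable
    pool_of_group = {}
    available = list(range(len(internal)))
    for groups, kappa in cfg.coupled_groups:
        sizes = [cfg.group_sizes[g] for g in groups]
        psize = cfg.pool_size or max(1, min(min(sizes), len(internal)))
        if psize > len(available):
            raise ContractError("not enough internal branches for disjoint "
                                "coupling pools")
        pool_idx = rng.choice(len(available), size=psize, replace=False)
        pool = [internal[available[int(i)]] for i in pool_idx]
        for i in sorted((int(i) for i in pool_idx), reverse=True):
            del available[i]
        for g in groups:
            pool_of_group[g] = (pool, kappa)

    # primary branch per character: coupled groups cycle over their pool
    # (guaranteeing full coverage), others round-robin over a shuffled
    # internal-branch list so every internal branch gains signal
    order = list(rng.permutation(len(internal)))
    rr = 0
    primary = [None] * cfg.n_chars
    counter_in_group = {}
    for j in range(cfg.n_chars):
        gi = group_of.get(j)
        if gi in pool_of_group:
            pool, kappa = pool_of_group[gi]
            k = counter_in_group.get(gi, 0)
            counter_in_group[gi] = k + 1
            if rng.random() < kappa:
                primary[j] = pool[k % len(pool)]
                continue
        primary[j] = internal[order[rr % len(internal)]]
        rr += 1

    tix = {lab: i for i, lab in enumerate(taxa)}
    codes = np.zeros((cfg.n_taxa, cfg.n_chars), dtype=np.int8)
    truth = TruthLog(tree=t)
    for j in range(cfg.n_chars):
        events = []
        col = np.zeros(cfg.n_taxa, dtype=np.int8)
        below = [tix[x] for x in primary[j]]
        col[below] = 1
        events.append((primary[j], 0, 1))
        # extra states for multistate characters, painted below random branches
        for s in range(2, cfg.n_states):
            extra_branch = all_branches[int(rng.integers(0, len(all_branches)))]
            members = [tix[x] for x in extra_branch]
            old = int(col[members[0]])
            col[members] = s
            events.append((extra_branch, old, s))
        # homoplasy: convergent flips below random branches
        for _ in range(rng.poisson(cfg.homoplasy)):
            branch = all_branches[int(rng.integers(0, len(all_branches)))]
            members = [tix[x] for x in branch]
            old = int(col[members[0]])
            new = (old + 1) % max(cfg.n_states, 2)
            col[members] = new
            events.append((branch, old, new))
        codes[:, j] = col
        truth.events[j + 1] = events

    if cfg.missing_rate > 0:
        blank = rng.random(codes.shape) < cfg.missing_rate
        codes[blank] = -1

    matrix = CharacterMatrix(taxa, codes)
    return matrix, truth


def simulate(cfg: SimulationConfig):
    """Draw a tree and a matrix in one call.

    The tree is uniform over rooted labelled shapes, re-rooted on the
    outgroup terminal (so truth-log branch clades match the rooting used
    downstream).  Tree and matrix randomness are split off the single
    configuration seed.  Returns ``(tree, matrix, truth_log)``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_tree, s_mat = ss.spawn(2)
    tree = random_tree(cfg.n_taxa, s_tree,
                       labels=cfg.taxon_labels()).rooted_on(cfg.outgroup)
    matrix, truth = simulate_matrix(tree, cfg, rng=np.random.default_rng(s_mat))
    return tree, matrix, truth
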