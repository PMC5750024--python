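"""Co-change structure among anatomical character groups.

Given the branches x groups binary event matrix, this module quantifies
which groups tend to change on the same branches of the tree:

* Kulczynski (binary, second form) similarity between group event vectors,
* single-linkage hierarchical clustering of the groups,
* ANOSIM (rank-based permutation test) between designated classes of
  groups (by default the female thelycum groups vs the male petasma
  groups),
* non-metric multidimensional scaling with Kruskal stress-1.

Distances are 1 - similarity throughout; ANOSIM and single linkage depend
only on distance ranks, so this monotone conversion is inconsequential.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .errors import ContractError
from .mapping import GroupEventMatrix

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Binary similarity
# --------------------------------------------------------------------------

def kulczynski_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Kulczynski-2 similarity of two presence/absence vectors.

    S = 1/2 (a/(a+b) + a/(a+c)) with a shared presences and b, c
    unilateral presences.  When one vector has no presences at all the
    marginal fraction is undefined; such pairs return 0 with a warning
    (both-empty input is an error).
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ContractError("vectors must have equal length")
    a = int((x & y).sum())
    b = int((x & ~y).sum())
    c = int((~x & y).sum())
    if a + b == 0 and a + c == 0:
        raise ContractError("similarity undefined for two all-zero vectors")
    if a + b == 0 or a + c == 0:
        log.warning("kulczynski: one vector has no presences; similarity 0")
        return 0.0
    return 0.5 * (a / (a + b) + a / (a + c))


def dice_similarity(x, y) -> float:
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    a = int((x & y).sum())
    denom = int(x.sum()) + int(y.sum())
    if denom == 0:
        raise ContractError("similarity undefined for two all-zero vectors")
    return 2 * a / denom


def jaccard_similarity(x, y) -> float:
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    union = int((x | y).sum())
    if union == 0:
        raise ContractError("similarity undefined for two all-zero vectors")
    return int((x & y).sum()) / union


_INDICES = {"kulczynski": kulczynski_similarity,
            "dice": dice_similarity,
            "jaccard": jaccard_similarity}


@dataclass
class SimilarityMatrix:
    """Symmetric groups x groups similarity with its distance companion."""

    similarity: pd.DataFrame

    @property
    def distance(self) -> pd.DataFrame:
        return 1.0 - self.similarity

    @property
    def labels(self) -> list:
        return list(self.similarity.index)

    def condensed_distance(self) -> np.ndarray:
        d = self.distance.to_numpy()
        return squareform(d, checks=False)

    def to_tsv(self, path) -> None:
        self.similarity.to_csv(path, sep="\t", index_label="group")


def group_similarity(gem: GroupEventMatrix,
                     index: str = "kulczynski") -> SimilarityMatrix:
    """Pairwise similarity between the group event vectors.

    Groups with no events are reported and excluded; fewer than two usable
    groups is an error.
    """
    fn = _INDICES[index]
    df = gem.df
    usable = [g for g in df.columns if df[g].sum() > 0]
    dropped = [g for g in df.columns if g not in usable]
    if dropped:
        log.warning("groups with zero events excluded: %s", dropped)
    if len(usable) < 2:
        raise ContractError("need at least two groups with events")
    k = len(usable)
    sim = np.eye(k)
    for i, j in itertools.combinations(range(k), 2):
        s = fn(df[usable[i]].to_numpy(), df[usable[j]].to_numpy())
        sim[i, j] = sim[j, i] = s
    return SimilarityMatrix(pd.DataFrame(sim, index=usable, columns=usable))


# --------------------------------------------------------------------------
# Single-linkage clustering
# --------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Single-linkage merge tree over the group labels."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def merges(self) -> list:
        """(member set, member set, height) per merge, in order."""
        n = len(self.labels)
        members = {i: frozenset([self.labels[i]]) for i in range(n)}
        out = []
        for step, (a, b, h, _) in enumerate(self.linkage):
            sa, sb = members[int(a)], members[int(b)]
            out.append((sa, sb, float(h)))
            members[n + step] = sa | sb
        return out

    def cophenetic(self) -> pd.DataFrame:
        d = hierarchy.cophenet(self.linkage)
        return pd.DataFrame(squareform(d), index=self.labels,
                            columns=self.labels)

    def cluster_of(self, label: str, height: float) -> frozenset:
        """The cluster containing ``label`` just after cutting at ``height``."""
        flat = hierarchy.fcluster(self.linkage, t=height, criterion="distance")
        mine = flat[self.labels.index(label)]
        return frozenset(l for l, c in zip(self.labels, flat) if c == mine)

    def newick(self) -> str:
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        text = {i: self.labels[i] for i in range(n)}
        for step, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            text[n + step] = f"({text[a]}:{la:g},{text[b]}:{lb:g})"
            height[n + step] = h
        return text[n + len(self.linkage) - 1] + ";"

    def to_tsv(self, path) -> None:
        rows = [{"merge": i + 1,
                 "cluster_a": ",".join(sorted(a)),
                 "cluster_b": ",".join(sorted(b)),
                 "height": h}
                for i, (a, b, h) in enumerate(self.merges())]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def single_linkage(sim: SimilarityMatrix) -> Dendrogram:
    """Agglomerative nearest-neighbour clustering on 1 - similarity."""
    d = sim.distance.to_numpy()
    if not np.allclose(d, d.T):
        raise ContractError("distance matrix must be symmetric")
    Z = hierarchy.linkage(sim.condensed_distance(), method="single")
    return Dendrogram(Z, sim.labels)


# --------------------------------------------------------------------------
# ANOSIM
# --------------------------------------------------------------------------

@dataclass
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int
    exact: bool
    seed: int = None


def _anosim_r(ranks: np.ndarray, labels: np.ndarray) -> float:
    n = labels.size
    iu = np.triu_indices(n, 1)
    within = labels[iu[0]] == labels[iu[1]]
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return (rb - rw) / (n * (n - 1) / 4.0)


def anosim(distance: pd.DataFrame, factor: dict, n_perm: int = 9999,
           seed: int = None, exact_cap: int = 20000) -> AnosimResult:
    """Analysis of similarities between classes of items.

    ``factor`` maps each item label to its class.  R compares mean
    between-class and within-class ranks of the pairwise distances.  The
    null distribution enumerates all distinct label assignments when their
    number is at most ``exact_cap`` (exact p = proportion of assignments
    with R >= observed); otherwise ``n_perm`` random permutations with the
    add-one estimator p = (1 + #{R_perm >= R_obs}) / (1 + n_perm).
    """
    items = list(distance.index)
    labels = np.array([factor[i] for i in items])
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ContractError("ANOSIM needs at least two classes")
    if (counts < 1).any():
        raise ContractError("every class needs at least one member")
    d = distance.to_numpy()
    n = len(items)
    iu = np.triu_indices(n, 1)
    ranks = rankdata(d[iu])
    r_obs = _anosim_r(ranks, labels)

    total = math.factorial(n)
    for c in counts:
        total //= math.factorial(int(c))
    if total <= exact_cap:
        count = 0
        for perm in _multiset_permutations(list(labels)):
            if _anosim_r(ranks, np.array(perm)) >= r_obs - 1e-12:
                count += 1
        return AnosimResult(r_obs, count / total, total, True, seed)
    if seed is None:
        raise ContractError("sampled ANOSIM requires a seed")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _anosim_r(ranks, rng.permutation(labels)) >= r_obs - 1e-12:
            hits += 1
    return AnosimResult(r_obs, (1 + hits) / (1 + n_perm), n_perm, False, seed)


def _multiset_permutations(items: list):
    """All distinct orderings of a multiset (lexicographic)."""
    items = sorted(items)
    n = len(items)
    while True:
        yield list(items)
        # next lexicographic permutation
        i = n - 2
        while i >= 0 and items[i] >= items[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while items[j] <= items[i]:
            j -= 1
        items[i], items[j] = items[j], items[i]
        items[i + 1:] = reversed(items[i + 1:])


# --------------------------------------------------------------------------
# Non-metric MDS
# --------------------------------------------------------------------------

@dataclass
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float  # Kruskal stress-1 of the best restart
    restart_stresses: list = field(default_factory=list)


def kruskal_stress1(distance: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 with the primary approach to ties.

    Disparities are the isotonic regression of the embedded distances on
    the rank order of the target dissimilarities; tied targets may take
    any relative order (they are pre-sorted by embedded distance).
    """
    target = squareform(np.asarray(distance), checks=False)
    emb = squareform(_pairwise(coords), checks=False)
    order = np.lexsort((emb, target))
    iso = IsotonicRegression()
    dhat = np.empty_like(emb)
    dhat[order] = iso.fit_transform(np.arange(order.size), emb[order])
    denom = float((emb ** 2).sum())
    if denom == 0:
        return 1.0
    return float(np.sqrt(((emb - dhat) ** 2).sum() / denom))


def _pairwise(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def nmds(distance: pd.DataFrame, dims: int = 2, n_restarts: int = 8,
         max_iter: int = 300, seed: int = None) -> NmdsResult:
    """Non-metric MDS embedding minimising Kruskal stress-1.

    Runs ``n_restarts`` independent optimisations from random starts and
    returns the configuration with the lowest stress; the reported stress
    of the best restart is therefore never above any individual restart.
    """
    if seed is None:
        raise ContractError("nmds requires a seed")
    items = list(distance.index)
    d = distance.to_numpy()
    if dims >= len(items):
        raise ContractError("dims must be smaller than the item count")
    rng = np.random.default_rng(seed)
    best_coords, stresses = None, []
    for _ in range(max(1, n_restarts)):
        rs = int(rng.integers(0, 2**31 - 1))
        model = MDS(n_components=dims, metric="precomputed", metric_mds=False,
                    n_init=1, max_iter=max_iter, random_state=rs,
                    init="random", normalized_stress=False, eps=1e-9)
        coords = model.fit_transform(d)
        s1 = kruskal_stress1(d, coords)
        stresses.append(s1)
        if best_coords is None or s1 < min(stresses[:-1], default=np.inf):
            best_coords = coords
    best = float(min(stresses))
    cols = [f"dim{i + 1}" for i in range(dims)]
    return NmdsResult(pd.DataFrame(best_coords, index=items, columns=cols),
                      best, stresses)
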