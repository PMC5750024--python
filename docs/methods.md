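# Methods

## Scope and model

`cladecoev` analyses matrices of unordered (non-additive), equally
weighted discrete characters under the parsimony criterion. A state change
between any two states costs one step times the character weight; `?`
(missing) and `-` (inapplicable) are both treated as "any observed state"
at the leaf — they can never add steps. The two sentinels are kept apart
in the data model but are deliberately identical downstream, following
common TNT/NONA practice for morphological matrices where the distinction
is documentary rather than analytical.

Parsimony length is a function of the unrooted topology, so all searching
is over unrooted trees; rooting on the outgroup terminal is presentational
and applied when results are packaged.

## Search

Scoring uses the Fitch downpass on state bitmasks, vectorised across all
characters with numpy, which makes a single tree evaluation cheap enough
for the exact search to rescore partial trees from scratch.

`branch_and_bound_search` is exact implicit enumeration: depth-first
sequential taxon addition, taxa ordered by decreasing total character
conflict (pairwise mismatch count) so that partial lengths grow early.
The admissible lower bound is the partial-tree length plus one weighted
step for every state present only among unplaced taxa: any such state must
still arise at least once. The initial upper bound is a greedy stepwise
addition tree. Branches are pruned only when they strictly exceed the
bound, and ties at the optimum are all retained, so the returned set is
provably *all* most-parsimonious topologies. Search refuses more than 25
taxa by default (the exact-search ceiling); `heuristic_search` —
random-addition greedy insertion plus NNI swapping, deterministic under
its seed — covers anything larger and all bootstrap replicates.

On matrices with strong hierarchical signal (the regime this package
targets) the exact search visits a few hundred partial trees at 17 taxa
and finishes in well under a second; random noise matrices degrade it
gracefully toward exhaustive behaviour.

## Homoplasy indices

Per character, the minimum steps over all trees is (number of observed
states − 1) and the maximum is (non-missing codings − count of the most
frequent state); both formulas are validated in the tests against scoring
every topology at small taxon counts. Ensemble CI and RI are kept as
exact rationals and rendered as integers with round-half-up, because the
source programs print integer percentages. By default all characters
enter the sums; a flag excludes parsimony-uninformative characters, since
WINCLADA and TNT conventions differ on this point. When no character
varies the indices are undefined and an error is raised rather than a
NaN returned. When every character can reach its minimum on every tree
(Σg = Σm) the retention index is reported as 1 by convention.

## Clade support

**Bootstrap.** Each pseudoreplicate resamples character columns with
replacement to the original count and re-searches (heuristic by default,
exact optionally). When a replicate yields k optimal trees, each of its
clades receives weight 1/k, avoiding overcounting of ambiguous
replicates. Clades are identified by their ingroup taxon set (the side of
the split not containing the outgroup). The replicate count defaults to
1 000 at desk scale; the study-scale 10 000 is a configuration choice.

**Bremer decay.** For every clade of the strict consensus of the optimal
trees, a constrained branch and bound finds the best length among trees
*not* containing that clade; the decay is the difference. This is exact
and can only be equal to or larger than what a save-suboptimal-trees
protocol reports; that protocol is nevertheless available
(`suboptimal_trees`) as a compatibility mode. Decays above the cap
(default 8) are reported as "≥ cap". Clades absent from the strict
consensus have decay 0 by definition.

**Significance.** A clade is flagged significant when bootstrap ≥ 80 %
and decay ≥ 3, both thresholds inclusive; the rule is a conjunction, so
neither value can rescue the other.

## Change mapping

Ancestral states use unit-cost Sankoff tables (down-costs, up-costs and
per-node minimal-state sets), which for unordered characters coincide
with Fitch reconstruction. Three mapping conventions are exposed:

- **unambiguous** (default): a change is emitted on a branch only when
  the minimal-state sets of its two ends are disjoint, i.e. the change is
  present in every minimum reconstruction. This is the reliable-
  synapomorphy display convention and is validated in the tests against
  enumeration of all minimum reconstructions on small trees.
- **acctran / deltran**: a single minimum reconstruction is chosen in a
  preorder pass; whenever a state choice is cost-neutral, acctran prefers
  the change on the current (rootward) branch and deltran defers it.
  Both are exact minimum reconstructions, so per-character event counts
  equal the character's Fitch length. Remaining ties break toward the
  smallest state index, making the output deterministic.

Terminal branches count as events by default (autapomorphies are real
changes); a flag restricts mapping to internal branches for displays that
list synapomorphies on clades only. The default mode is a documented
choice: the analyses this package reproduces do not state their
resolution rule, so the conservative unambiguous mapping is the default
and both resolutions are switches.

## Coevolution statistics

The branches × groups event matrix is binary by default ("did any
character of this group change on this branch?"). Kulczynski-2 is the
default similarity (the binary form used by the PAST package); Dice and
Jaccard are alternates. A pair where one group has no presences returns
similarity 0 with a warning; two empty vectors are an error. Distance is
1 − similarity with no square-root transform: ANOSIM and single linkage
depend only on ranks, so any monotone conversion gives identical results.

ANOSIM enumerates all distinct label assignments exactly when their
number is at most a cap (default 20 000), reporting p as the proportion
of assignments with R at least the observed value; beyond the cap it
samples permutations and uses the add-one estimator
p = (1 + hits)/(1 + permutations). The default factor contrasts the
female (thelycum) groups against the male (petasma) groups; the factor is
an explicit input and results are labelled with it, since any such test
depends on the chosen classes.

NMDS runs scikit-learn's non-metric SMACOF from several random starts and
reports the configuration minimising Kruskal stress-1, computed here with
isotonic regression using the primary approach to ties (tied
dissimilarities may take any relative order). The best-restart stress is
by construction no worse than any individual restart.

## Synthetic data

The generator defines the conditions every stage is tested under: 17
terminal taxa (one outgroup), 75 characters in the eight anatomical
groups (9, 16, 14, 9, 2, 6, 8, 10 characters for S6, AS7, PS7, S8, PI,
LA, PM, PE — 74 grouped plus one free character), mostly binary states,
homoplasy 0.04 expected extra changes per character (ensemble CI in the
mid-to-high nineties, matching the regime of well-curated copulatory-
structure matrices), and an optional 2 % missing rate.

Character placement samples branches directly rather than simulating a
clock-like Markov process: trees here carry no meaningful branch lengths
and direct placement gives exact control of the consistency index and of
coupling. Uncoupled characters are assigned round-robin over a shuffled
list of internal branches, so every internal branch receives signal and
zero-homoplasy matrices are perfect phylogenies with a uniquely
recoverable topology. Coupled group sets share a pool of internal
branches (pools of different sets are disjoint); with coupling
probability κ = 1 the groups' event vectors are identical by
construction. Homoplasy adds Poisson-distributed extra flips below random
branches. All randomness derives from one seed through a splittable
generator.

What the generator does **not** emulate: correlated character states
within a group (characters are independent given their branch),
inapplicable-character logic (a lobe absent in one species making its
sub-characters unscorable), and uneven taxon sampling. Passing tests
therefore demonstrate correctness of the machinery and recoverability
under the stated regime, not robustness to those real-data complications.

## Numerical and design notes

- Weighted lengths are compared with a 1e-9 tolerance; with the default
  integer weights all arithmetic is effectively exact and totals are
  returned as ints.
- Zero-length branches are retained, not collapsed; strict/majority
  consensus provides the collapsed summaries where needed.
- Tree identity is the set of non-trivial bipartitions, canonicalised by
  the side not containing the lexicographically smallest taxon, so
  duplicate topologies are never double-counted regardless of rooting.
- The default character-group layout covers characters 1–74 in eight
  groups; the published description of the same layout is internally
  inconsistent (it announces nine groups and 75 characters), so the
  layout ships as an editable YAML config rather than a constant, and the
  partitions are defined as unions of groups (thelycum = S6+AS7+PS7+S8,
  petasma = PI+LA+PM+PE).
- Problem sizes in the test-suite and acceptance script (5–7 taxa for
  enumeration oracles, 12–17 taxa for pipeline runs, 200–300 bootstrap
  replicates, 20 coupling replicates) are chosen so the whole validation
  battery represents each regime while remaining a desk-scale
  computation; every size is recorded alongside the reported value.

## Known limitations

- Exact search is factorial in the worst case; beyond ~25 taxa only the
  heuristic is offered, and its optimum is a lower-bounded estimate, not
  a guarantee.
- Ordered/additive characters, step matrices, implied weighting and
  likelihood/Bayesian inference are out of scope.
- Bremer decay via constrained exact search is exponential per clade on
  noisy matrices; the cap bounds the damage but large caps on large noisy
  matrices are slow.
- ANOSIM p-values below 1/(number of distinct assignments) are
  unreachable with few groups (eight groups in two classes of four give a
  floor of 2/70 ≈ 0.029).
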