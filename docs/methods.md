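# Methods

## Model and assumptions

The package models evolution of binary traits on a rooted binary
tree-based network. Three assumptions define explainability: traits are
homoplasy-free (a single origin each), traits are never lost along
vertical (support) edges once acquired, and traits may cross the
explicitly marked transfer edges. The edge partition {E_S, E_T} is part of
the input — the network is an "LGT network" in which donors and
recipients are identified, not merely a topology that admits some
tree-based embedding. All networks are required to be time-consistent:
donor and recipient of a transfer must be contemporaneous. Subdivision
(degree-2) nodes are rejected in networks and permitted only inside
support-tree views, which is what makes the base tree well defined.

The two validators implement equivalent characterizations of an
explaining labeling: the defining conditions (leaf agreement, no loss,
single origin by reachability) and the connectivity form (carriers of each
character weakly connected with a unique source; non-carriers either
absent or a connected piece of the support tree containing the root).
Their equivalence is exercised exhaustively in the tests over every
labeling of every ≤8-node network on two characters — by the node-count
arithmetic 2L−1+2T this family is exactly: the single node, trees on 2–4
leaves, and the cherry with one transfer in either direction.

## Recognition

For each character c the forced-absent set F_c (nodes with a
support-descendant leaf lacking c) is computed by one post-order sweep;
ancestor closure of F_c follows from the no-loss rule. The network minus
F_c is then scanned for a source whose reachable set covers every
surviving leaf — only in-degree-0 nodes need checking, since any witness
is reachable from one. "Leaves" here means original leaves surviving the
deletion; internal nodes turned into sinks carry no taxa and impose no
constraint. Two conventions the model leaves open are fixed as follows
and covered by tests:

* a character possessed by **no** taxon is vacuously explained with an
  empty carrier set (the single-origin condition quantifies over an empty
  set);
* a character possessed by **every** taxon has F_c = ∅ and the root as
  origin, so every node is labeled with it.

When several sources qualify, the smallest node id wins; any choice
yields a valid labeling, and determinism keeps outputs reproducible.

## Tree completion

Completion starts from a copy of the input tree, a no-loss pre-labeling
(Fitch by default: a character sits exactly on the maximal clades whose
leaves all carry it), and an initial time map: all leaves at time 0,
internal nodes at distinct positive integers increasing with subtree
height, so every parent strictly predates its children. Characters are
processed in declaration order. For each character the first-appearance
nodes are sorted by decreasing time (ties — only possible between leaves,
which share time 0 — broken by node id) and chained: the donor attachment
below the older node a_i is found by walking down first-support-children
until the first node no younger than the recipient a_{i+1}; leaves at
time 0 guarantee termination. Both edges are subdivided and the new pair
placed at time (min(τ(w′), τ(a′)) + τ(a))/2, which lies strictly inside
both subdivided edges, so time consistency is preserved inductively. New
nodes are labeled with the intersection of their edge's endpoints plus
the transferred character, which preserves the no-loss property and never
touches original nodes — the pre-labeling survives node for node. Times
are exact dyadic rationals (`fractions.Fraction`); the float tolerance
(1e-9) only matters for maps read from files.

Exactly |X_c| − 1 transfers are inserted per character, which is what
makes the worst-case count exact rather than an upper bound: insertions
for one character never change the first-appearance sets of another
(inserted nodes take label intersections, so they carry a character only
when both endpoints already did).

Bounds: each term of max_c(|A_c|−1) and Σ_c(|A_c|−1) is clamped at zero,
because characters carried by all leaves or by none have no
first-appearance node and need no transfers — the unclamped formulas
implicitly assume |A_c| ≥ 1.

Pruning scans transfer edges newest-first (greedy over-placements tend to
sit high in the tree), removes an edge whenever the reduced network is
still recognized and time-feasible, and restarts after each removal; the
result is a network in which every transfer is necessary. Newest-first is
a documented choice — any order yields a minimal-irreducible network, not
necessarily a minimum one. The suboptimality of greedy-plus-pruning is
real but rare at small sizes: the seeded sweeps in the tests find it on
roughly 1 instance in 20.

## Worst-case machinery

`worstcase_instance(k)` builds the complete binary tree of depth k with
left/right children marked 0/1; giving character c_i to the subtree of
every 1-marked node at depth i makes the leaves realize exactly the 2^k
subsets of C, with 2^(i−1) first-appearance nodes at level i. This level
labeling coincides with the Fitch labeling of the resulting taxa.
Completion therefore adds Σ(2^(i−1) − 1) = 2^k − k − 1 transfers. The
coarser closed form 2^k − (k−1) is also asserted as an upper budget; the
two printed forms differ by 2 and the construction realizes the sharper
evaluated sum. The lower-bound side counts nodes that are a
first-appearance of at least one character under Fitch: for any binary
tree over the power-set taxa this is at least a third of the leaves, so
some character has ≥ 2^k/(3k) first-appearances and 2^k/(3k) − 1
transfers are unavoidable. For k ≤ 3 that bound is below 1 and the
exhaustive cross-checks are correspondingly mild; the machinery, not the
small-k numbers, is the point.

## Oracles and the recombination comparison

`brute_force_is_ptn` enumerates, per character, every carrier set
compatible with the leaves and tests the connectivity characterization —
independent of the recognition path, and feasible to 14 nodes.
`brute_force_min_completion` searches breadth-first over sequences of
transfer insertions between ordered pairs of support edges. Two
reductions keep it usable: states are de-duplicated by an exact placement
key (each inserted node is identified by the original edge it subdivides
and its rank along it — base-tree nodes are labeled, so equal keys mean
equal networks), and states are pruned by a sound per-character deficit
(each insertion can merge at most two weakly connected components of the
stripped graph, so components-minus-one more transfers are unavoidable).
Guards: 5 leaves, 3 characters, 4 transfers.

The recombination (ARG) side encodes taxa as bit strings in character
order. A reticulation's string must be a d-crossover of its parents':
decomposable into at most d+1 blocks copied alternately from either
parent. Empty blocks are allowed ("at most d crossovers"), matching the
minimum-needed reasoning; a strict mode with exactly d alternation
indices is also provided, and the greedy minimal-switch scan is checked
against exhaustive index enumeration property-wise. `is_arg_explainable`
backtracks over internal-node strings in topological order, pre-bounding
each node by the AND of the leaves it reaches through tree-edge-only
paths (a pure optimization, verified against naive product enumeration on
tiny cases). The inclusion check of PTNs into ARGs with |C| crossovers
moves characters whose origin sits on a reticulation down to the
reticulation's child (top-down, so chains resolve) before converting the
labeling to bit strings.

One model boundary is worth stating: a character carried by *every* taxon
is inexpressible in an ARG at any d, because the root is pinned to the
all-zeros string and at most one tree edge may flip a character — so both
root edges would need the flip. Such characters are therefore excluded
from the random-instance inclusion sweeps; the checker itself returns
False on them honestly.

## Synthetic data

Random trees grow by uniform attachment (subdivide a uniformly chosen
edge, hang the next leaf); random taxa draw each taxon-character bit
i.i.d. Bernoulli. Default study conditions in the seeded sweeps: networks
with 2–4 leaves and 0–2 transfers on 1–3 characters at densities
{0.3, 0.5, 0.7} for recognition cross-checks (sizes at which the
exhaustive oracle is instant), and trees with 3–5 leaves on 2–3
characters at density 0.5 for completion and pruning, with the exhaustive
optimum attempted up to 3 transfers. These generators emulate presence/
absence matrices with independent traits; they do not emulate correlated
trait gain, rate heterogeneity across lineages, observation error, or
missing data, so passing tests certify the combinatorial algorithms, not
robustness to noisy real matrices.

## File formats

Networks use an extended-Newick dialect: a reticulation appears as two
occurrences of the same `#Hn` label, the occurrence whose branch carries
`[&type=transfer]` hanging under the donor; the untagged occurrence
carries the reticulation's subtree. The model's standing assumption that
the support/transfer partition is known forces the file format to carry
it explicitly, and no established serialization does, hence the
documented dialect (plain Newick round-trips as a transfer-free network).
Character matrices are 0/1 TSV/CSV with a `taxon` header column; no
missing-data symbol is supported. Labelings and time maps are two-column
TSV.

## Known limitations

* Minimum completion and minimum reconstruction are only approximated
  (the |C| factor is the proven guarantee); the exact search is a test
  oracle, not a production feature.
* Binary characters only; no Dollo-style losses, no multi-state traits,
  no branch lengths, no non-binary degrees.
* The pruning order is a heuristic; no constant-factor guarantee is
  claimed or tested beyond the |C| bound.
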