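# ptn — perfect transfer networks

Tools for inferring horizontal gene transfer (HGT) from **binary character
data** rather than from sequences. Ancient transfers are notoriously hard to
see in alignments — mutations erase the signal — but traits with unique
origins that are rarely lost once gained (transposable elements, metabolic
markers, organelles, expression of a gene) can survive where sequence
similarity does not. When two distant clades share such a trait, a transfer
is a natural explanation.

The package is aimed at people studying character evolution on phylogenies:
it implements the *perfect transfer network* (PTN) model, a direct
generalization of perfect phylogenies to tree-based networks.

## The model

Taxa are subsets of a character set *C*. A **tree-based network**
*G = (V, E_S ∪ E_T)* is a rooted binary DAG whose *support edges* E_S span
every node as a tree (vertical descent) and whose *transfer edges* E_T each
point into a reticulation node (horizontal transfer); suppressing the
degree-2 nodes of the support tree gives the *base tree*. A network is
biologically feasible when a **time-consistent map** τ exists: τ strictly
decreases along support edges and is equal across transfer edges — donor
and recipient must have co-existed.

A C-labeling *l* of the nodes **explains** the taxa when

1. *l*(v) = σ(v) on every leaf,
2. for every support edge (u,v): c ∈ l(u) ⇒ c ∈ l(v) (*never lost once
   acquired*),
3. for every character c, a unique node of V_c(l) = {v : c ∈ l(v)} reaches
   every node of V_c(l) inside G[V_c(l)] (*single origin*; transfers may
   carry c horizontally).

(G, σ) is a **perfect transfer network** for the taxa if such a labeling
exists. On a tree this is exactly a perfect phylogeny.

What the package computes:

* **Recognition** — decide in O(|C|·|V|²) whether a given network explains
  the taxa, returning an explicit labeling as certificate. The key object
  is the *forced-absent set* F_c: nodes with a support-descendant leaf
  lacking c can never carry c, and after deleting F_c it suffices to find
  one source reaching every remaining leaf.
* **Tree completion** — add time-consistent transfer edges to *any* species
  tree (optionally constrained by a no-loss pre-labeling, Fitch by default)
  so that the result explains the taxa; chains the *first-appearance* nodes
  of each character, oldest donor first.
* **Transfer bounds and pruning** — with A_c the Fitch first-appearance
  sets, any completion of T needs at least max_c(|A_c|−1) transfers and the
  greedy uses at most Σ_c(|A_c|−1), a |C|-approximation; a post-process
  prunes transfers whose removal keeps the network explainable.
* **Worst-case constructions** — the power-set taxa 2^C on a level-labeled
  complete binary tree, completed with exactly 2^k − k − 1 transfers, and
  the 2^k/(3k) − 1 lower bound via first-appearance counting.
* **Model comparison oracles** — brute-force recognition and minimum
  completion, and a d-crossover checker for ancestral recombination graphs
  (ARGs), including the small networks separating the two models.

## Worked example

Four γ-proteobacteria scored for two traits: a transposase family `tnpA`
and a metabolic marker `metX`.

```
$ cat chars.csv
taxon,tnpA,metX
Ecoli,1,1
Sente,1,1
Vchol,0,1
Paeru,1,0

$ cat tree.nwk
((Ecoli,Sente),(Vchol,Paeru));

$ ptn bounds -t tree.nwk -m chars.csv
lower=1 upper=2
```

Each trait sits on two separated clades (`tnpA` on {Ecoli,Sente} and
{Paeru}; `metX` on {Ecoli,Sente} and {Vchol}), so at least one and at most
two transfers are needed. Completing the tree:

```
$ ptn complete -t tree.nwk -m chars.csv --prune -o demo
transfers=2 lower=1 upper=2

$ cat demo.enwk
(((Ecoli,#H1[&type=transfer]),(Sente,#H2[&type=transfer])),((Paeru)#H1,(Vchol)#H2));
```

Two transfers were added and pruning kept both: one donates `tnpA` to the
Paeru lineage, the other `metX` to the Vchol lineage, and no single
transfer could carry both (the donors live in different subtrees). Each
`#Hn` pair marks a reticulation; the occurrence tagged
`[&type=transfer]` hangs under the donor. `demo.labels.tsv` holds the
explaining labeling and `demo.times.tsv` the time-consistency witness.

The worst-case construction at k = 3:

```
$ ptn worstcase -k 3 -o wc3
transfers=4 proof_bound=4 statement_bound=6 lemma15=-0.111...
```

All 8 subsets of 3 characters placed on a complete binary tree need
exactly 2³ − 3 − 1 = 4 transfers under the level labeling.

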