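"""Worst-case constructions for the transfer-minimization problem.

The taxa set demanding the most transfers is the full power set of the
characters.  On a complete binary tree with 2^k leaves one can label the
two children of every internal node 0 and 1; giving character ``c_i`` to
the subtree of every 1-marked node at depth *i* makes the leaves realize
exactly the 2^k subsets, with ``2^(i-1)`` first-appearance nodes per
level.  Running the greedy completion on this instance yields a network
with exactly ``2^k - k - 1`` transfers (the evaluated per-level sum; the
coarser closed form ``2^k - (k - 1)`` bounds it from above).

Conversely, for *any* binary tree over the power-set taxa at least a third
of the leaves force distinct first-appearance nodes, so some character has
at least ``2^k / (3k)`` of them and ``2^k/(3k) - 1`` transfers are
unavoidable.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import completion
from .netmodel import CharacterSet, PhyloNetwork, TaxaTable, network_from_edges


def _taxon_name(bits: str) -> str:
    return "s" + bits


def powerset_taxa(k: int) -> tuple[CharacterSet, TaxaTable]:
    """All 2^k subsets of ``{c_1..c_k}`` as taxa, one per bit string.

    Taxon ``s<b_1..b_k>`` possesses ``c_i`` iff bit i is 1.
    """
    if not 1 <= k <= 20:
        raise ValueError("k must be between 1 and 20")
    chars = CharacterSet([f"c{i}" for i in range(1, k + 1)])
    taxa = {}
    for x in range(2**k):
        bits = format(x, f"0{k}b")
        taxa[_taxon_name(bits)] = {f"c{i + 1}" for i in range(k) if bits[i] == "1"}
    return chars, TaxaTable(chars, taxa)


@dataclass
class WorstCaseInstance:
    """Complete binary tree over the power-set taxa with its level labeling.

    ``marks`` maps each non-root node to its 0/1 mark (left child 0, right
    child 1); ``levels[i]`` lists the nodes at edge-distance ``i + 1`` from
    the root.  The labeling gives ``c_i`` to the subtree below every
    1-marked node of level ``i`` and nowhere else.
    """

    tree: PhyloNetwork
    labeling: dict
    characters: CharacterSet
    taxa: TaxaTable
    marks: dict
    levels: list


def worstcase_instance(k: int) -> WorstCaseInstance:
    """Build the k-level complete binary tree whose leaves realize 2^C."""
    chars, taxa = powerset_taxa(k)
    edges = []
    leaf_map = {}
    marks = {}
    levels: list[list[str]] = [[] for _ in range(k)]

    def node_id(path: str) -> str:
        return "r" if not path else "v" + path

    paths = [""]
    for depth in range(k):
        nxt = []
        for p in paths:
            for bit in "01":
                child = p + bit
                edges.append((node_id(p), node_id(child)))
                marks[node_id(child)] = int(bit)
                levels[depth].append(node_id(child))
                nxt.append(child)
        paths = nxt
    for p in paths:
        leaf_map[node_id(p)] = _taxon_name(p)
    tree = network_from_edges(edges, leaf_map, root="r")
    labeling = {}
    for v in tree.nodes:
        path = "" if v == "r" else v[1:]
        labeling[v] = frozenset(f"c{i + 1}" for i in range(len(path)) if path[i] == "1")
    completion.check_no_loss(tree, labeling)
    return WorstCaseInstance(tree, labeling, chars, taxa, marks, levels)


def worstcase_ptn(k: int) -> PhyloNetwork:
    """Complete the worst-case instance with its level labeling.

    The greedy adds ``2^(i-1) - 1`` transfers for level ``i``, i.e.
    ``2^k - k - 1`` in total, within the stated ``2^k - (k-1)`` budget.
    """
    inst = worstcase_instance(k)
    result = completion.complete(inst.tree, inst.taxa, prelabel=inst.labeling)
    return result.network


def lemma15_lower_bound(k: int) -> float:
    """The unavoidable transfer count ``2^k / (3k) - 1`` for power-set taxa."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2**k / (3 * k) - 1


def first_appearance_total(tree: PhyloNetwork, taxa: TaxaTable) -> int:
    """|A(T)|: nodes that are a first-appearance of >= 1 character under the
    Fitch labeling.  For any binary tree over power-set taxa this is at
    least a third of the leaf count."""
    k = len(taxa.characters)
    leaf_taxa = {tree.leaf_map[v] for v in tree.leaves}
    if leaf_taxa != set(taxa) or len(taxa) != 2**k:
        raise ValueError("tree leaves must be in bijection with the power-set taxa")
    lam = completion.fitch_labeling(tree, taxa)
    tmap = completion.initial_time_map(tree)
    nodes = set()
    for c in taxa.characters:
        nodes.update(completion.first_appearances(tree, lam, c, tmap))
    return len(nodes)
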