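"""Brute-force references, instance generators and model-comparison gadgets.

Everything here exists to cross-check the polynomial algorithms at desk
scale: an exhaustive per-character search over carrier sets (the
recognition oracle), a breadth-first search over transfer insertions (the
minimum-completion oracle), seeded random trees and character matrices,
and the two small networks separating perfect transfer networks from
ancestral recombination graphs (ARGs) together with a *d*-crossover
explainability checker.

In the ARG model each node carries an m-bit string (bit j = character
c_j), the root is all zeros, tree edges may only flip 0 -> 1 with at most
one flipping edge per character, and a reticulation's string must be a
*d*-crossover of its parents' strings: at most ``d`` alternation points
between blocks copied from either parent.
"""

from __future__ import annotations

import itertools
import logging
import random
from typing import Optional

import networkx as nx

from . import completion, recognition
from .netmodel import (
    SUPPORT,
    TRANSFER,
    CharacterSet,
    PhyloNetwork,
    TaxaTable,
    _require_valid,
    network_from_edges,
    reachable_set,
    time_consistency_feasible,
)

logger = logging.getLogger("ptn")

_IS_PTN_NODE_GUARD = 14


# ---------------------------------------------------------------------------
# brute-force recognition
# ---------------------------------------------------------------------------


def brute_force_is_ptn(net: PhyloNetwork, taxa: TaxaTable) -> bool:
    """Exhaustive recognition: for each character, try every carrier set.

    Leaf membership is forced by the taxa; all subsets of internal nodes
    are enumerated and tested against the connectivity characterization
    (carriers connected with a unique source; non-carriers either empty or
    a connected piece of the support tree containing the root).
    """
    _require_valid(net)
    g = net.graph
    if g.number_of_nodes() > _IS_PTN_NODE_GUARD:
        raise ValueError(f"network too large for brute force (> {_IS_PTN_NODE_GUARD} nodes)")
    internal = sorted(v for v in g.nodes if not net.is_leaf(v))
    support = set(net.support_edges)
    all_nodes = set(g.nodes)

    def valid_carrier_set(vc: set) -> bool:
        sub = g.subgraph(vc)
        if not nx.is_weakly_connected(sub):
            return False
        if sum(1 for v in vc if sub.in_degree(v) == 0) != 1:
            return False
        comp = all_nodes - vc
        if not comp:
            return True
        if net.root not in comp:
            return False
        sup = nx.Graph()
        sup.add_nodes_from(comp)
        sup.add_edges_from((u, v) for (u, v) in support if u in comp and v in comp)
        return nx.is_connected(sup)

    for c in taxa.characters:
        forced_in = {v for v in g.nodes if net.is_leaf(v) and c in taxa[net.leaf_map[v]]}
        if not forced_in:
            continue  # empty carrier set is vacuously valid
        ok = False
        for r in range(len(internal) + 1):
            for extra in itertools.combinations(internal, r):
                if valid_carrier_set(forced_in | set(extra)):
                    ok = True
                    break
            if ok:
                break
        if not ok:
            return False
    return True


# ---------------------------------------------------------------------------
# brute-force minimum completion
# ---------------------------------------------------------------------------


def _char_deficit(net: PhyloNetwork, taxa: TaxaTable, c: str) -> int:
    """Lower bound on the transfers still needed to explain character ``c``.

    After stripping the forced-absent set, each insertion can merge at most
    two weakly connected components (the new transfer edge is the only new
    link), so (leaf-bearing components - 1) more transfers are unavoidable;
    a connected remainder that still has no source reaching every leaf
    needs at least one.
    """
    fc = recognition.forced_absent(net, taxa, c)
    keep = set(net.graph.nodes) - fc
    if not keep:
        return 0
    sub = net.graph.subgraph(keep)
    leaf_comps = [comp for comp in nx.weakly_connected_components(sub) if any(net.is_leaf(v) for v in comp)]
    if len(leaf_comps) > 1:
        return len(leaf_comps) - 1
    leaves_c = {v for v in keep if net.is_leaf(v)}
    for v in keep:
        if sub.in_degree(v) == 0 and leaves_c <= reachable_set(sub, v):
            return 0
    return 1


def _deficit(net: PhyloNetwork, taxa: TaxaTable) -> int:
    return max((_char_deficit(net, taxa, c) for c in taxa.characters), default=0)


def _placement_key(net: PhyloNetwork, original: frozenset) -> tuple:
    """Canonical description of a state reached by transfer insertions.

    Every inserted node subdivides exactly one edge of the original tree;
    identifying it by (original child below, rank from the top) makes two
    states with equal keys identical up to inserted-node renaming.
    """
    pos = {}
    for v in original:
        u = net.support_parent(v)
        if u is None:
            continue
        chain = []
        while u not in original:
            chain.append(u)
            u = net.support_parent(u)
        for rank, w in enumerate(reversed(chain)):
            pos[w] = (v, rank)
    return tuple(sorted((pos[w], pos[a]) for (w, a) in net.transfer_edges))


def brute_force_min_completion(
    tree: PhyloNetwork, taxa: TaxaTable, max_t: int
) -> Optional[int]:
    """Minimum number of transfers turning ``tree`` into a PTN, or ``None``
    if more than ``max_t`` are needed.

    Breadth-first search over sequences of transfer insertions between all
    ordered pairs of support-tree edges, pruning time-inconsistent states
    and states whose per-character deficit exceeds the remaining budget,
    and de-duplicating equal transfer placements.  Exponential; guarded to
    <= 5 leaves, <= 3 characters, max_t <= 4.
    """
    if len(tree.leaves) > 5 or len(taxa.characters) > 3 or max_t > 4:
        raise ValueError("instance exceeds brute-force guards (5 leaves / 3 characters / 4 transfers)")
    if _deficit(tree, taxa) == 0:
        return 0
    original = frozenset(tree.nodes)
    frontier = [tree]
    seen: set = set()
    for t in range(1, max_t + 1):
        states: list[PhyloNetwork] = []
        for g in frontier:
            edges = g.support_edges
            for donor, recip in itertools.permutations(edges, 2):
                h = g.copy()
                try:
                    completion.insert_transfer(h, None, None, donor, recip)
                except ValueError:
                    continue
                key = _placement_key(h, original)
                if key in seen:
                    continue
                seen.add(key)
                if not time_consistency_feasible(h)[0]:
                    continue
                deficit = _deficit(h, taxa)
                if deficit == 0:
                    return t
                if t + deficit > max_t:
                    continue
                states.append(h)
        frontier = states
    return None


# ---------------------------------------------------------------------------
# random instance generators (seeded, deterministic)
# ---------------------------------------------------------------------------


def random_tree(n_leaves: int, seed: int) -> PhyloNetwork:
    """Uniform-attachment random binary tree with leaves ``t1..tn``.

    Grown by repeatedly subdividing a uniformly chosen edge and hanging
    the next leaf off the new node; deterministic per seed.
    """
    if n_leaves < 1:
        raise ValueError("need at least one leaf")
    rng = random.Random(seed)
    if n_leaves == 1:
        net = PhyloNetwork()
        net.add_node("l1")
        net.root = "l1"
        net.leaf_map = {"l1": "t1"}
        return net
    net = PhyloNetwork()
    net.add_node("i0")
    net.root = "i0"
    for j in (1, 2):
        net.add_node(f"l{j}")
        net.add_edge("i0", f"l{j}", SUPPORT)
        net.leaf_map[f"l{j}"] = f"t{j}"
    for j in range(3, n_leaves + 1):
        u, v = rng.choice(sorted(net.support_edges))
        mid = f"i{j - 2}"
        leaf = f"l{j}"
        net.remove_edge(u, v)
        net.add_node(mid)
        net.add_edge(u, mid, SUPPORT)
        net.add_edge(mid, v, SUPPORT)
        net.add_node(leaf)
        net.add_edge(mid, leaf, SUPPORT)
        net.leaf_map[leaf] = f"t{j}"
    return net


def random_taxa(n: int, k: int, density: float, seed: int) -> tuple[CharacterSet, TaxaTable]:
    """Taxa ``t1..tn`` over ``c1..ck`` with i.i.d. Bernoulli(density) bits."""
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    rng = random.Random(seed)
    chars = CharacterSet([f"c{i}" for i in range(1, k + 1)])
    taxa = {
        f"t{j}": {c for c in chars if rng.random() < density}
        for j in range(1, n + 1)
    }
    return chars, TaxaTable(chars, taxa)


def random_network(n_leaves: int, n_transfers: int, seed: int) -> PhyloNetwork:
    """Random tree plus ``n_transfers`` random time-consistent transfer
    insertions (each sampled insertion is retried until feasible)."""
    rng = random.Random(seed)
    net = random_tree(n_leaves, rng.randrange(2**30))
    added = 0
    attempts = 0
    while added < n_transfers and attempts < 200:
        attempts += 1
        edges = sorted(net.support_edges)
        donor, recip = rng.sample(edges, 2)
        trial = net.copy()
        try:
            completion.insert_transfer(trial, None, None, donor, recip)
        except ValueError:
            continue
        if not time_consistency_feasible(trial)[0]:
            continue
        net = trial
        added += 1
    return net


# ---------------------------------------------------------------------------
# model-comparison gadgets
# ---------------------------------------------------------------------------


def gadget_fig3_1(d: int) -> tuple[PhyloNetwork, TaxaTable]:
    """Five-leaf network on d+2 characters that is a PTN but needs d+1
    crossovers as an ARG.

    Two empty-set leaves sit under the support path feeding the single
    reticulation; the two full-character leaves hang off the donor side,
    which forces every 0->1 flip onto one root edge, so the reticulation
    must take the alternating odd-characters string from its all-zeros
    support parent and all-ones transfer parent.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    m = d + 2
    chars = CharacterSet([f"c{i}" for i in range(1, m + 1)])
    full = set(chars)
    odd = {f"c{i}" for i in range(1, m + 1) if i % 2 == 1}
    taxa = TaxaTable(
        chars,
        {"empty1": set(), "empty2": set(), "allc_up": full, "allc_low": full, "odd": odd},
    )
    edges = [
        ("rho", "x"), ("rho", "y"),
        ("x", "empty1"), ("x", "x2"),
        ("x2", "empty2"), ("x2", "ret"),
        ("y", "allc_up"), ("y", "dn"),
        ("dn", "allc_low"), ("dn", "ret", TRANSFER),
        ("ret", "odd"),
    ]
    leaf_map = {n: n for n in ("empty1", "empty2", "allc_up", "allc_low", "odd")}
    return network_from_edges(edges, leaf_map, root="rho"), taxa


def gadget_fig3_2() -> tuple[PhyloNetwork, TaxaTable]:
    """Five-leaf network on two characters explainable with single
    crossovers but not a PTN.

    Each character sits on two leaves; one carrier leaf of c1 shares its
    parent with the support path to an empty leaf, so the no-loss rule
    would force c1 into that empty leaf.  As an ARG the empty leaf's
    reticulation parent simply crosses its 10 and 01 grandparents over to
    00.
    """
    chars = CharacterSet(["c1", "c2"])
    taxa = TaxaTable(
        chars,
        {"p1": {"c1"}, "q1": {"c1"}, "p2": {"c2"}, "q2": {"c2"}, "none": set()},
    )
    edges = [
        ("rho", "u"), ("rho", "w"),
        ("u", "p1"), ("u", "x"),
        ("x", "q1"), ("x", "ret"),
        ("w", "p2"), ("w", "y"),
        ("y", "q2"), ("y", "ret", TRANSFER),
        ("ret", "none"),
    ]
    leaf_map = {n: n for n in ("p1", "q1", "p2", "q2", "none")}
    return network_from_edges(edges, leaf_map, root="rho"), taxa


# ---------------------------------------------------------------------------
# d-crossover machinery
# ---------------------------------------------------------------------------


def is_d_crossover(b: str, x: str, y: str, d: int) -> bool:
    """True iff ``b`` splits into at most ``d + 1`` consecutive blocks
    copied alternately from ``x`` and ``y`` (either may start; empty blocks
    permitted, i.e. "at most d crossovers").

    Greedy minimal-switch scan: track which parents can supply the current
    block and count forced alternations.
    """
    if not (len(b) == len(x) == len(y)):
        raise ValueError("strings must have equal length")
    if d < 0:
        raise ValueError("d must be >= 0")
    current = {"x", "y"}
    switches = 0
    for j in range(len(b)):
        avail = set()
        if b[j] == x[j]:
            avail.add("x")
        if b[j] == y[j]:
            avail.add("y")
        if not avail:
            return False
        if current & avail:
            current = current & avail
        else:
            switches += 1
            current = avail
    return switches <= d


def exhaustive_d_crossover(b: str, x: str, y: str, d: int, strict: bool = False) -> bool:
    """Reference checker enumerating crossover index placements.

    ``strict`` demands exactly ``d`` strictly increasing indices (the
    literal alternation formula); the relaxed default accepts any number
    up to ``d`` and is what the greedy scan implements.
    """
    if not (len(b) == len(x) == len(y)):
        raise ValueError("strings must have equal length")
    n = len(b)
    dds = [d] if strict else list(range(d + 1))
    for dd in dds:
        for idx in itertools.combinations(range(n + 1), dd):
            bounds = [0, *idx, n]
            for start in (x, y):
                other = y if start is x else x
                built = []
                for t in range(len(bounds) - 1):
                    src = start if t % 2 == 0 else other
                    built.append(src[bounds[t]: bounds[t + 1]])
                if "".join(built) == b:
                    return True
    return False


# ---------------------------------------------------------------------------
# ARG explainability
# ---------------------------------------------------------------------------


def _beta(subset: frozenset, chars: CharacterSet) -> int:
    bits = 0
    for i, c in enumerate(chars):
        if c in subset:
            bits |= 1 << i
    return bits


def _bitstring(value: int, m: int) -> str:
    return "".join("1" if value >> i & 1 else "0" for i in range(m))


def _arg_labeling_ok(net: PhyloNetwork, taxa: TaxaTable, f: dict, d: int) -> bool:
    """Check a complete binary labeling against the ARG conditions."""
    chars = taxa.characters
    m = len(chars)
    if f[net.root] != 0:
        return False
    for v in net.leaves:
        if f[v] != _beta(taxa[net.leaf_map[v]], chars):
            return False
    flips = [0] * m
    for (u, v) in net.graph.edges:
        if net.is_reticulation(v):
            continue  # tree edges only
        if f[u] & ~f[v]:
            return False  # a 1 -> 0 loss on a tree edge
        gained = f[v] & ~f[u]
        for i in range(m):
            if gained >> i & 1:
                flips[i] += 1
                if flips[i] > 1:
                    return False
    for v in net.nodes:
        if not net.is_reticulation(v):
            continue
        pu, pw = net.parents(v)
        if not is_d_crossover(_bitstring(f[v], m), _bitstring(f[pu], m), _bitstring(f[pw], m), d):
            return False
    return True


def _tree_edge_masks(net: PhyloNetwork, taxa: TaxaTable) -> dict:
    """Upper bound on each node's bits: AND over the leaves it reaches by
    tree-edge-only paths (a 1 anywhere else would be lost on a tree edge)."""
    chars = taxa.characters
    full = (1 << len(chars)) - 1
    mask: dict[str, int] = {}
    for v in reversed(list(nx.topological_sort(net.graph))):
        if net.is_leaf(v):
            mask[v] = _beta(taxa[net.leaf_map[v]], chars)
            continue
        m = full
        for w in net.graph.successors(v):
            if not net.is_reticulation(w):
                m &= mask[w]
        mask[v] = m
    return mask


def is_arg_explainable(net: PhyloNetwork, taxa: TaxaTable, d: int, naive: bool = False) -> bool:
    """Does some binary labeling explain the taxa with d-crossovers?

    Exhaustive over internal-node bit strings with the root pinned to all
    zeros and leaves to their taxa.  The default path backtracks in
    topological order and pre-constrains each node by the AND of the
    leaves below it (a pure optimization); ``naive`` enumerates the full
    product and exists as the independent reference for tiny cases.
    """
    _require_valid(net)
    chars = taxa.characters
    m = len(chars)
    free = [v for v in net.nodes if v != net.root and not net.is_leaf(v)]
    if (2**m) ** len(free) > 10**8:
        raise ValueError("instance exceeds the ARG enumeration guard")
    fixed = {net.root: 0}
    for v in net.leaves:
        fixed[v] = _beta(taxa[net.leaf_map[v]], chars)

    if naive:
        full = (1 << m) - 1
        for values in itertools.product(range(full + 1), repeat=len(free)):
            f = dict(fixed)
            f.update(zip(free, values))
            if _arg_labeling_ok(net, taxa, f, d):
                return True
        return False

    masks = _tree_edge_masks(net, taxa)
    order = list(nx.topological_sort(net.graph))
    f: dict[str, int] = {}
    flips = [0] * m

    def options(v: str):
        if v in fixed:
            return (fixed[v],)
        sub = masks[v]
        opts = []
        s = sub
        while True:
            opts.append(s)
            if s == 0:
                break
            s = (s - 1) & sub
        return opts

    def consistent(v: str, val: int) -> Optional[list[int]]:
        """Check in-edges of v; return the list of newly flipped bits or
        None on violation."""
        preds = net.parents(v)
        if net.is_reticulation(v):
            pu, pw = preds
            if not is_d_crossover(_bitstring(val, m), _bitstring(f[pu], m), _bitstring(f[pw], m), d):
                return None
            return []
        gained_bits: list[int] = []
        for u in preds:  # at most one (tree edge)
            if f[u] & ~val:
                return None
            gained = val & ~f[u]
            for i in range(m):
                if gained >> i & 1:
                    if flips[i] >= 1:
                        return None
                    gained_bits.append(i)
        return gained_bits

    def search(idx: int) -> bool:
        if idx == len(order):
            return True
        v = order[idx]
        for val in options(v):
            got = consistent(v, val)
            if got is None:
                continue
            f[v] = val
            for i in got:
                flips[i] += 1
            if search(idx + 1):
                return True
            for i in got:
                flips[i] -= 1
            del f[v]
        return False

    return search(0)


def ptn_implies_arg_infty_check(net: PhyloNetwork, taxa: TaxaTable) -> bool:
    """Verify that this PTN is also an ARG with m = |C| crossovers.

    Takes the recognition labeling, moves any character whose origin sits
    on a reticulation down to the reticulation's child (processing nodes
    top-down, so chains of reticulations resolve), converts the result to
    bit strings and checks the ARG conditions at d = m.  Characters
    possessed by every taxon make the root non-zero, which no ARG labeling
    can express; the check then honestly returns False.
    """
    labeling = recognition.recognize(net, taxa)
    if labeling is None:
        raise ValueError("input is not a PTN for the given taxa")
    lab = {v: set(s) for v, s in labeling.items()}
    for v in nx.topological_sort(net.graph):
        if not net.is_reticulation(v):
            continue
        pu, pw = net.parents(v)
        lab[v] &= lab[pu] | lab[pw]
    chars = taxa.characters
    f = {v: _beta(frozenset(s), chars) for v, s in lab.items()}
    return _arg_labeling_ok(net, taxa, f, len(chars))
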