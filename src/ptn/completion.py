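"""Greedy time-consistent tree completion.

Any species tree can be turned into a perfect transfer network for any
taxa set, even when the internal nodes are pre-labeled: for each character
the maximal clades already carrying it (the *first-appearance* subtrees)
are chained together with transfer edges, oldest donor first, choosing
donor attachment points so the whole construction stays time-consistent.

The module also provides the Fitch labeling (a character sits exactly on
the maximal clades whose leaves all carry it), the transfer-count bounds
it implies — at least ``max_c(|A_c|-1)`` and at most ``sum_c(|A_c|-1)``
transfers, making the greedy a ``|C|``-approximation — and a pruning
post-process that discards transfers whose removal leaves the network
explainable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from fractions import Fraction
from typing import NamedTuple, Optional

from . import netmodel, recognition
from .netmodel import (
    SUPPORT,
    TRANSFER,
    PhyloNetwork,
    TaxaTable,
    TimeMap,
    _require_valid,
    fresh_sub_id,
    reset_sub_counter,
)

logger = logging.getLogger("ptn")


@dataclass
class TransferInsertionRecord:
    """One transfer insertion: both support edges are subdivided, creating a
    donor node ``w_hat`` (tree node) and a recipient ``a_hat``
    (reticulation), joined by a transfer edge at a common time."""

    donor_edge: tuple
    recipient_edge: tuple
    donor_node: str
    recipient_node: str
    time: object
    character: Optional[str]


class CompletionResult(NamedTuple):
    network: PhyloNetwork
    labeling: dict
    time_map: TimeMap
    records: list


def _check_tree(t: PhyloNetwork) -> None:
    _require_valid(t)
    if t.transfer_edges:
        raise ValueError("input must be a tree (no transfer edges)")


def fitch_labeling(tree: PhyloNetwork, taxa: TaxaTable) -> dict[str, frozenset]:
    """Label each node with the characters shared by *all* leaves below it.

    Equivalently the intersection of the children's labels; this is the
    natural no-loss pre-labeling placing every character on its maximal
    clades.
    """
    _check_tree(tree)
    label: dict[str, frozenset] = {}
    order = _postorder(tree)
    for v in order:
        if tree.is_leaf(v):
            label[v] = frozenset(taxa[tree.leaf_map[v]])
        else:
            kids = tree.support_children(v)
            inter = frozenset(label[kids[0]])
            for w in kids[1:]:
                inter &= label[w]
            label[v] = inter
    return label


def check_no_loss(net: PhyloNetwork, labeling) -> None:
    """Raise unless the labeling is monotone along support edges."""
    for (u, v) in net.support_edges:
        if not labeling[u] <= labeling[v]:
            raise ValueError(f"labeling loses {sorted(labeling[u] - labeling[v])} on edge ({u!r},{v!r})")


def first_appearances(net: PhyloNetwork, labeling, c: str, tmap: TimeMap) -> list[str]:
    """X_c: nodes whose support parent lacks ``c`` while their entire support
    subtree (themselves included) carries it, sorted by decreasing time
    (ties broken by node id).  Members are pairwise incomparable."""
    check_no_loss(net, labeling)
    all_below: dict[str, bool] = {}
    for v in _postorder(net):
        has = c in labeling[v]
        all_below[v] = has and all(all_below[w] for w in net.support_children(v))
    out = []
    for v in net.nodes:
        p = net.support_parent(v)
        if p is None:
            continue
        if c not in labeling[p] and all_below[v]:
            out.append(v)
    out.sort(key=lambda v: (-tmap[v], v))
    return out


def initial_time_map(tree: PhyloNetwork) -> TimeMap:
    """All leaves at time 0; internal nodes get distinct positive integer
    times, each parent strictly older than its children (assigned upward by
    subtree height, so no two internal nodes share a time)."""
    _check_tree(tree)
    height: dict[str, int] = {}
    for v in _postorder(tree):
        kids = tree.support_children(v)
        height[v] = 0 if not kids else 1 + max(height[w] for w in kids)
    internal = sorted((v for v in tree.nodes if not tree.is_leaf(v)), key=lambda v: (height[v], v))
    tau = {v: Fraction(0) for v in tree.leaves}
    for i, v in enumerate(internal):
        tau[v] = Fraction(i + 1)
    return TimeMap(tau)


def insert_transfer(
    net: PhyloNetwork,
    labeling: Optional[dict],
    tmap: Optional[TimeMap],
    donor_edge: tuple,
    recipient_edge: tuple,
    c: Optional[str] = None,
) -> TransferInsertionRecord:
    """Subdivide two support edges and join the new nodes by a transfer.

    The donor edge (w', w) must straddle the recipient child's time:
    tau(w') > tau(a) >= tau(w), with tau(a') > tau(a); the created pair is
    placed at the midpoint (min(tau(w'), tau(a')) + tau(a)) / 2, which lies
    strictly inside both subdivided edges, so the network stays valid and
    time-consistent.  New nodes inherit the intersection of their edge's
    endpoint labels plus the transferred character.

    ``labeling``/``tmap`` may be ``None`` for purely topological insertion
    (used by the brute-force completion oracle).
    """
    wp, w = donor_edge
    ap, a = recipient_edge
    if donor_edge == recipient_edge:
        raise ValueError("donor and recipient edge must differ")
    for (u, v) in (donor_edge, recipient_edge):
        if not net.graph.has_edge(u, v) or net.edge_kind(u, v) != SUPPORT:
            raise ValueError(f"({u!r},{v!r}) is not a support edge")
    t_new = None
    if tmap is not None:
        if not (tmap[wp] > tmap[a] and tmap[ap] > tmap[a]):
            raise ValueError("time precondition violated: donor/recipient parents must predate the recipient child")
        t_new = (min(tmap[wp], tmap[ap]) + tmap[a]) / 2
    w_hat = fresh_sub_id(net)
    net.add_node(w_hat)
    a_hat = fresh_sub_id(net)
    net.add_node(a_hat)
    net.remove_edge(wp, w)
    net.add_edge(wp, w_hat, SUPPORT)
    net.add_edge(w_hat, w, SUPPORT)
    net.remove_edge(ap, a)
    net.add_edge(ap, a_hat, SUPPORT)
    net.add_edge(a_hat, a, SUPPORT)
    net.add_edge(w_hat, a_hat, TRANSFER)
    if tmap is not None:
        tmap[w_hat] = t_new
        tmap[a_hat] = t_new
    if labeling is not None:
        extra = frozenset() if c is None else frozenset({c})
        labeling[w_hat] = (labeling[w] & labeling[wp]) | extra
        labeling[a_hat] = (labeling[a] & labeling[ap]) | extra
    return TransferInsertionRecord(donor_edge, recipient_edge, w_hat, a_hat, t_new, c)


def complete(
    tree: PhyloNetwork,
    taxa: TaxaTable,
    prelabel: Optional[dict] = None,
) -> CompletionResult:
    """Add time-consistent transfers so the tree explains the taxa.

    Characters are processed in declaration order.  For each, the
    first-appearance nodes are chained oldest-first: the donor attachment
    is found by walking down from the older node to the first descendant no
    younger than the recipient, so donor and recipient can be joined at a
    common time.  The pre-labeling (Fitch by default) is preserved on every
    original tree node; exactly ``|X_c| - 1`` transfers are added per
    character.
    """
    _check_tree(tree)
    if prelabel is None:
        prelabel = fitch_labeling(tree, taxa)
    else:
        missing = [v for v in tree.nodes if v not in prelabel]
        if missing:
            raise ValueError(f"pre-labeling missing nodes {sorted(missing)}")
        check_no_loss(tree, prelabel)
        for v in tree.leaves:
            if frozenset(prelabel[v]) != taxa[tree.leaf_map[v]]:
                raise ValueError(f"pre-labeling disagrees with taxa on leaf {v!r}")
    net = tree.copy()
    labeling = {v: frozenset(prelabel[v]) for v in net.nodes}
    tmap = initial_time_map(tree)
    reset_sub_counter()
    records: list[TransferInsertionRecord] = []
    for c in taxa.characters:
        xc = first_appearances(net, labeling, c, tmap)
        for i in range(len(xc) - 1):
            a_i, a_next = xc[i], xc[i + 1]
            w = a_i
            while tmap[w] > tmap[a_next]:
                w = net.support_children(w)[0]
            wp = net.support_parent(w)
            ap = net.support_parent(a_next)
            rec = insert_transfer(net, labeling, tmap, (wp, w), (ap, a_next), c)
            records.append(rec)
    logger.debug("completion added %d transfers", len(records))
    return CompletionResult(net, labeling, tmap, records)


def transfer_bounds(tree: PhyloNetwork, taxa: TaxaTable) -> tuple[int, int]:
    """Transfer-count bounds from the Fitch first-appearance sets A_c.

    Any network with this base tree needs at least ``max_c(|A_c| - 1)``
    transfers; the greedy needs at most ``sum_c(|A_c| - 1)``.  Characters
    possessed by all leaves (or none) have no first-appearance node and
    need no transfers, so each term is clamped at zero.
    """
    _check_tree(tree)
    lam = fitch_labeling(tree, taxa)
    tmap = initial_time_map(tree)
    counts = [len(first_appearances(tree, lam, c, tmap)) for c in taxa.characters]
    terms = [max(0, k - 1) for k in counts]
    if not terms:
        return 0, 0
    return max(terms), sum(terms)


def remove_transfer(net: PhyloNetwork, edge: tuple) -> PhyloNetwork:
    """Copy of ``net`` with one transfer edge removed and the two resulting
    subdivision nodes suppressed."""
    u, v = edge
    if net.edge_kind(u, v) != TRANSFER:
        raise ValueError(f"({u!r},{v!r}) is not a transfer edge")
    out = net.copy()
    g = out.graph
    g.remove_edge(u, v)
    for x in (u, v):
        if g.in_degree(x) == 1 and g.out_degree(x) == 1:
            (p,) = g.predecessors(x)
            (ch,) = g.successors(x)
            kind = g.edges[x, ch]["kind"]
            g.remove_node(x)
            g.add_edge(p, ch, kind=kind)
        elif x == out.root and g.out_degree(x) == 1:
            (ch,) = g.successors(x)
            g.remove_node(x)
            out.root = ch
    return out


def _transfer_order(net: PhyloNetwork) -> list[tuple]:
    """Transfer edges, newest insertion first (ids ``sub_<n>`` encode age);
    ties and foreign ids fall back to lexicographic order."""

    def key(edge):
        m = re.match(r"sub_(\d+)$", edge[0])
        return (int(m.group(1)) if m else -1, edge)

    return sorted(net.transfer_edges, key=key, reverse=True)


def prune_transfers(net: PhyloNetwork, taxa: TaxaTable) -> PhyloNetwork:
    """Greedily drop transfers whose removal keeps the network a PTN.

    Scans newest-first (greedy over-placements tend to sit high in the
    tree), restarting after each committed removal; the result is a PTN in
    which every remaining transfer is necessary.  Idempotent.
    """
    if recognition.recognize(net, taxa) is None:
        raise ValueError("input network is not a PTN for the given taxa")
    current = net.copy()
    changed = True
    while changed:
        changed = False
        for edge in _transfer_order(current):
            candidate = remove_transfer(current, edge)
            if recognition.recognize(candidate, taxa) is None:
                continue
            if not netmodel.time_consistency_feasible(candidate)[0]:
                continue
            current = candidate
            changed = True
            break
    return current


def _postorder(net: PhyloNetwork) -> list[str]:
    order: list[str] = []
    stack = [net.root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(net.support_children(v))
    order.reverse()
    return order
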