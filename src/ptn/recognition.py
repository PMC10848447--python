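"""Recognition of perfect transfer networks.

A tree-based network *G* with leaf taxa explains its taxa when some
C-labeling *l* of its nodes satisfies, for every character *c*: leaves
carry exactly their observed characters, *c* is never lost along support
edges, and the nodes carrying *c* are reachable from a single origin
inside the induced subgraph (transfers may carry *c* horizontally).

Recognition exploits the *forced-absent* sets: a node that has a
support-tree descendant leaf lacking *c* can never carry *c* (losses are
forbidden), so F_c can be stripped off and it suffices to look for one
source of the remaining graph that reaches all remaining leaves.  This
yields a polynomial-time decision procedure with an explicit labeling as
certificate.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional

import networkx as nx

from .netmodel import (
    SUPPORT,
    PhyloNetwork,
    TaxaTable,
    _require_valid,
    reachable_set,
)

logger = logging.getLogger("ptn")

#: a C-labeling: node id -> frozenset of characters
CLabeling = Mapping[str, frozenset]


def forced_absent(net: PhyloNetwork, taxa: TaxaTable, c: str) -> set:
    """F_c: nodes with a support-tree descendant leaf that lacks ``c``.

    Computed by one post-order sweep of the support tree; the result is
    closed under support-tree ancestors (if a node is forced absent, so is
    every node above it).
    """
    if c not in taxa.characters:
        raise KeyError(f"unknown character {c!r}")
    forced: set = set()
    # iterative post-order over the support tree
    order: list[str] = []
    stack = [net.root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(net.support_children(v))
    for v in reversed(order):
        if net.is_leaf(v):
            if c not in taxa[net.leaf_map[v]]:
                forced.add(v)
        elif any(w in forced for w in net.support_children(v)):
            forced.add(v)
    return forced


def _recognize(net: PhyloNetwork, taxa: TaxaTable):
    """Core of the recognition algorithm.

    Returns ``(labeling, None)`` on success or ``(None, c)`` where ``c`` is
    the first character with no valid origin.
    """
    _require_valid(net)
    missing = [t for t in net.leaf_map.values() if t not in taxa]
    if missing:
        raise ValueError(f"leaf taxa not in table: {sorted(missing)}")
    label: dict[str, set] = {v: set() for v in net.nodes}
    g = net.graph
    for c in taxa.characters:
        fc = forced_absent(net, taxa, c)
        keep = set(g.nodes) - fc
        if not keep:
            # character possessed by no leaf: vacuously explained, V_c empty
            continue
        sub = g.subgraph(keep)
        leaves_c = {v for v in keep if net.is_leaf(v)}
        sources = sorted(v for v in keep if sub.in_degree(v) == 0)
        origin = None
        for v in sources:
            r = reachable_set(sub, v)
            if leaves_c <= r:
                origin = v
                break
        if origin is None:
            return None, c
        for u in reachable_set(sub, origin):
            label[u].add(c)
    return {v: frozenset(s) for v, s in label.items()}, None


def recognize(net: PhyloNetwork, taxa: TaxaTable) -> Optional[dict]:
    """Decide whether ``(net, sigma)`` is a perfect transfer network.

    Returns an explaining C-labeling, or ``None`` if some character admits
    no origin.  When several sources of the stripped graph reach every
    remaining leaf, the smallest node id wins (any choice is valid; a
    deterministic one keeps outputs reproducible).
    """
    labeling, failing = _recognize(net, taxa)
    if labeling is None:
        logger.info("not a PTN: character %s has no origin", failing)
        return None
    return labeling


def explains(net: PhyloNetwork, taxa: TaxaTable, labeling: CLabeling) -> bool:
    """Validate a labeling against the defining conditions directly:
    leaf agreement, no loss along support edges, and a single origin
    reaching all carriers of each character."""
    _check_total(net, labeling)
    for v in net.leaves:
        if labeling[v] != taxa[net.leaf_map[v]]:
            return False
    for (u, v) in net.support_edges:
        if not labeling[u] <= labeling[v]:
            return False
    g = net.graph
    for c in taxa.characters:
        vc = {v for v in g.nodes if c in labeling[v]}
        if not vc:
            continue
        sub = g.subgraph(vc)
        sources = [v for v in vc if sub.in_degree(v) == 0]
        if len(sources) != 1:
            return False
        if reachable_set(sub, sources[0]) != vc:
            return False
    return True


def explains_by_connectivity(net: PhyloNetwork, taxa: TaxaTable, labeling: CLabeling) -> bool:
    """Validate a labeling via the equivalent connectivity characterization:
    per character, the carrier subgraph is connected with a unique source,
    and the non-carriers either vanish or form a connected piece of the
    support tree containing the root."""
    _check_total(net, labeling)
    for v in net.leaves:
        if labeling[v] != taxa[net.leaf_map[v]]:
            return False
    g = net.graph
    for c in taxa.characters:
        vc = {v for v in g.nodes if c in labeling[v]}
        if vc:
            sub = g.subgraph(vc)
            if not nx.is_weakly_connected(sub):
                return False
            if sum(1 for v in vc if sub.in_degree(v) == 0) != 1:
                return False
        comp = set(g.nodes) - vc
        if not comp:
            continue  # V = V_c branch
        if net.root not in comp:
            return False
        sup = nx.DiGraph()
        sup.add_nodes_from(comp)
        sup.add_edges_from((u, v) for (u, v) in net.support_edges if u in comp and v in comp)
        if not nx.is_weakly_connected(sup):
            return False
    return True


def _check_total(net: PhyloNetwork, labeling: CLabeling) -> None:
    missing = [v for v in net.nodes if v not in labeling]
    if missing:
        raise ValueError(f"partial labeling; missing nodes {sorted(missing)}")
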