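"""Core data model for tree-based phylogenetic networks.

A tree-based network is a rooted binary DAG whose edge set is partitioned
into *support* edges (vertical descent) and *transfer* edges (horizontal
gene transfer).  The support edges alone span every node and form the
*support tree*; suppressing its degree-2 subdivision nodes yields the
*base tree*.  Every transfer edge points into a reticulation node, which
therefore has exactly one vertical and one horizontal parent.  A network
is biologically feasible when a *time-consistent map* exists: node times
strictly decrease along support edges and are equal across transfer edges
(donor and recipient must have co-existed).

This module provides the containers (:class:`CharacterSet`,
:class:`TaxaTable`, :class:`PhyloNetwork`, :class:`TimeMap`), file I/O for
the extended-Newick dialect and binary character matrices, structural
validation, and the graph primitives the algorithmic modules build on.
"""

from __future__ import annotations

import io
import itertools
import logging
import os
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import networkx as nx
import pandas as pd

logger = logging.getLogger("ptn")

#: edge-kind flags
SUPPORT = "support"
TRANSFER = "transfer"

#: absolute tolerance for transfer-edge time equality.  Witness times are
#: constructed as exact dyadic rationals wherever possible (the completion
#: algorithm halves repeatedly), so this only matters for float input.
TIME_TOLERANCE = 1e-9

_LABEL_RE = re.compile(r"^([A-Za-z0-9_.\-]*)(?:#H(\d+))?$")


# ---------------------------------------------------------------------------
# node-id supply for subdivision nodes created by transfer insertion
# ---------------------------------------------------------------------------

_sub_counter = itertools.count()


def reset_sub_counter() -> None:
    """Restart the ``sub_<n>`` id sequence (called once per completion run)."""
    global _sub_counter
    _sub_counter = itertools.count()


def fresh_sub_id(net: "PhyloNetwork") -> str:
    """Next unused ``sub_<n>`` id for a node created by edge subdivision."""
    while True:
        nid = f"sub_{next(_sub_counter)}"
        if nid not in net:
            return nid


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


class CharacterSet(Sequence):
    """Ordered set of character identifiers ``c_1 .. c_m``.

    The order is stable: it fixes the bit positions used by the
    recombination-network (ARG) oracle.
    """

    def __init__(self, characters: Iterable[str]):
        chars = list(characters)
        if any(not c for c in chars):
            raise ValueError("character identifiers must be non-empty")
        if len(set(chars)) != len(chars):
            raise ValueError("character identifiers must be unique")
        self._chars = chars
        self._index = {c: i for i, c in enumerate(chars)}

    def __getitem__(self, i):
        return self._chars[i]

    def __len__(self) -> int:
        return len(self._chars)

    def __iter__(self) -> Iterator[str]:
        return iter(self._chars)

    def __contains__(self, c: object) -> bool:
        return c in self._index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CharacterSet) and self._chars == other._chars

    def index(self, c: str) -> int:  # type: ignore[override]
        return self._index[c]

    def __repr__(self) -> str:
        return f"CharacterSet({self._chars!r})"


class TaxaTable(Mapping):
    """Taxa as subsets of a :class:`CharacterSet`.

    Maps taxon name -> frozenset of characters.  Empty subsets are
    permitted (taxa with no character occur in the model-comparison
    gadgets); duplicate *character sets* are allowed, duplicate names are
    not (enforced by the dict).
    """

    def __init__(self, characters: CharacterSet, taxa: Mapping[str, Iterable[str]]):
        self.characters = characters
        self._taxa = {}
        for name, subset in taxa.items():
            fs = frozenset(subset)
            unknown = fs - set(characters)
            if unknown:
                raise ValueError(f"taxon {name!r} has unknown characters {sorted(unknown)}")
            self._taxa[name] = fs

    def __getitem__(self, name: str) -> frozenset:
        return self._taxa[name]

    def __len__(self) -> int:
        return len(self._taxa)

    def __iter__(self) -> Iterator[str]:
        return iter(self._taxa)

    def __repr__(self) -> str:
        return f"TaxaTable({len(self._taxa)} taxa on {len(self.characters)} characters)"


@dataclass
class TimeMap:
    """Node -> time witness of time consistency.

    Times may be floats or exact :class:`fractions.Fraction` values; the
    transfer-edge equality test uses :data:`TIME_TOLERANCE`.
    """

    tau: dict = field(default_factory=dict)

    def __getitem__(self, v):
        return self.tau[v]

    def __setitem__(self, v, t):
        self.tau[v] = t

    def __contains__(self, v) -> bool:
        return v in self.tau


class PhyloNetwork:
    """Rooted binary tree-based network with a support/transfer edge partition.

    Thin wrapper around a :class:`networkx.DiGraph`; each edge carries a
    ``kind`` attribute (:data:`SUPPORT` or :data:`TRANSFER`).  ``leaf_map``
    maps leaf node ids to taxon names (the S-map sigma).
    """

    def __init__(self):
        self.graph = nx.DiGraph()
        self.root: Optional[str] = None
        self.leaf_map: dict = {}

    # -- construction -------------------------------------------------
    def add_node(self, v: str) -> None:
        self.graph.add_node(v)

    def add_edge(self, u: str, v: str, kind: str = SUPPORT) -> None:
        if kind not in (SUPPORT, TRANSFER):
            raise ValueError(f"unknown edge kind {kind!r}")
        self.graph.add_edge(u, v, kind=kind)

    def remove_edge(self, u: str, v: str) -> None:
        self.graph.remove_edge(u, v)

    def remove_node(self, v: str) -> None:
        self.graph.remove_node(v)
        self.leaf_map.pop(v, None)

    def copy(self) -> "PhyloNetwork":
        new = PhyloNetwork()
        new.graph = self.graph.copy()
        new.root = self.root
        new.leaf_map = dict(self.leaf_map)
        return new

    # -- inspection ---------------------------------------------------
    def __contains__(self, v: object) -> bool:
        return v in self.graph

    @property
    def nodes(self):
        return self.graph.nodes

    def edge_kind(self, u: str, v: str) -> str:
        return self.graph.edges[u, v]["kind"]

    def edges(self, kind: Optional[str] = None):
        if kind is None:
            return list(self.graph.edges)
        return [(u, v) for u, v, k in self.graph.edges(data="kind") if k == kind]

    @property
    def support_edges(self):
        return self.edges(SUPPORT)

    @property
    def transfer_edges(self):
        return self.edges(TRANSFER)

    def children(self, v: str, kind: Optional[str] = None):
        if kind is None:
            return list(self.graph.successors(v))
        return [w for w in self.graph.successors(v) if self.graph.edges[v, w]["kind"] == kind]

    def parents(self, v: str, kind: Optional[str] = None):
        if kind is None:
            return list(self.graph.predecessors(v))
        return [u for u in self.graph.predecessors(v) if self.graph.edges[u, v]["kind"] == kind]

    def support_parent(self, v: str) -> Optional[str]:
        ps = self.parents(v, SUPPORT)
        return ps[0] if ps else None

    def support_children(self, v: str):
        return self.children(v, SUPPORT)

    def is_leaf(self, v: str) -> bool:
        return self.graph.out_degree(v) == 0

    def is_reticulation(self, v: str) -> bool:
        return self.graph.in_degree(v) == 2 and self.graph.out_degree(v) == 1

    @property
    def leaves(self):
        return [v for v in self.graph.nodes if self.graph.out_degree(v) == 0]

    def taxon(self, leaf: str) -> str:
        return self.leaf_map[leaf]

    def __repr__(self) -> str:
        return (
            f"PhyloNetwork({self.graph.number_of_nodes()} nodes, "
            f"{len(self.support_edges)} support / {len(self.transfer_edges)} transfer edges)"
        )


def network_from_edges(
    edges: Iterable[tuple],
    leaf_map: Mapping[str, str],
    root: Optional[str] = None,
) -> PhyloNetwork:
    """Build a network from ``(tail, head[, kind])`` tuples.

    Convenience constructor; the root defaults to the unique in-degree-0
    node.  Used heavily by the generators and the test suite.
    """
    net = PhyloNetwork()
    for e in edges:
        if len(e) == 2:
            u, v = e
            kind = SUPPORT
        else:
            u, v, kind = e
        net.add_node(u)
        net.add_node(v)
        net.add_edge(u, v, kind)
    if root is None:
        sources = [v for v in net.nodes if net.graph.in_degree(v) == 0]
        if len(sources) != 1:
            raise ValueError(f"cannot infer root: {len(sources)} in-degree-0 nodes")
        root = sources[0]
    net.root = root
    net.leaf_map = dict(leaf_map)
    return net


# ---------------------------------------------------------------------------
# character-matrix I/O
# ---------------------------------------------------------------------------


def read_character_matrix(source: Union[str, "os.PathLike"]) -> tuple[CharacterSet, TaxaTable]:
    """Read a taxa x characters 0/1 matrix (TSV or CSV).

    The header row is ``taxon,<c1>,<c2>,...``; the delimiter is sniffed
    from the header (tab wins over comma).  ``source`` may be a path or the
    raw text itself (anything containing a newline is treated as text).
    """
    if isinstance(source, (str, os.PathLike)) and "\n" not in str(source):
        with open(source, "r") as fh:
            text = fh.read()
    else:
        text = str(source)
    header = text.splitlines()[0] if text else ""
    sep = "\t" if "\t" in header else ","
    cols = header.split(sep)[1:]
    if len(set(cols)) != len(cols):
        raise ValueError("duplicate character names in header")
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, index_col=0)
    except Exception as exc:  # ragged rows, parser failures
        raise ValueError(f"malformed character matrix: {exc}") from exc
    chars = CharacterSet(str(c) for c in df.columns)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate taxon names: {dups}")
    taxa = {}
    for name, row in df.iterrows():
        subset = set()
        for c, cell in row.items():
            if pd.isna(cell):
                raise ValueError(f"ragged row for taxon {name!r}")
            cell = str(cell).strip()
            if cell not in ("0", "1"):
                raise ValueError(f"cell for taxon {name!r}, character {c!r} is {cell!r}; expected 0/1")
            if cell == "1":
                subset.add(str(c))
        taxa[str(name)] = subset
    return chars, TaxaTable(chars, taxa)


def write_character_matrix(taxa: TaxaTable, sep: str = "\t") -> str:
    """Serialize a :class:`TaxaTable` back to its tabular form."""
    lines = [sep.join(["taxon", *taxa.characters])]
    for name in taxa:
        bits = ["1" if c in taxa[name] else "0" for c in taxa.characters]
        lines.append(sep.join([name, *bits]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# extended-Newick I/O
#
# Dialect: a reticulation is written as two occurrences of the same "#Hn"
# label.  The occurrence whose incoming branch carries the annotation
# "[&type=transfer]" hangs under the transfer (donor) parent; the untagged
# occurrence hangs under the support parent and carries the reticulation's
# child subtree.  Plain Newick (no #H labels) parses to a network with an
# empty transfer-edge set, i.e. a tree.
# ---------------------------------------------------------------------------


_TOKEN_RE = re.compile(r"\(|\)|,|;|\[[^\]]*\]|[^(),;\[\]\s]+")


def _tokenize(text: str) -> list[str]:
    tokens = _TOKEN_RE.findall(text)
    if not tokens or tokens[-1] != ";":
        raise ValueError("newick string must end with ';'")
    return tokens


def parse_network(text: str, validate_result: bool = True) -> PhyloNetwork:
    """Parse an (extended) Newick string into a :class:`PhyloNetwork`."""
    tokens = _tokenize(text)
    pos = 0
    net = PhyloNetwork()
    counter = itertools.count()
    hybrids: dict[str, str] = {}          # #H id -> node id
    hybrid_occurrences: dict[str, list[bool]] = {}  # #H id -> transfer tags seen

    def new_node() -> str:
        nid = f"n{next(counter)}"
        net.add_node(nid)
        return nid

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def parse_subtree(parent: Optional[str]):
        nonlocal pos
        children: list = []
        if peek() == "(":
            pos += 1
            while True:
                parse_subtree_into(children)
                if peek() == ",":
                    pos += 1
                    continue
                if peek() == ")":
                    pos += 1
                    break
                raise ValueError(f"unexpected token {peek()!r}")
            has_children = True
        else:
            has_children = False
        label = ""
        if peek() not in ("(", ")", ",", ";", None) and not str(peek()).startswith("["):
            label = tokens[pos]
            pos += 1
        comment = ""
        if peek() is not None and str(peek()).startswith("["):
            comment = tokens[pos]
            pos += 1
        m = _LABEL_RE.match(label)
        if m is None:
            raise ValueError(f"malformed node label {label!r}")
        name, hid = m.group(1), m.group(2)
        is_transfer = "type=transfer" in comment
        if hid is not None:
            if hid in hybrids:
                node = hybrids[hid]
            else:
                node = new_node()
                hybrids[hid] = node
            hybrid_occurrences.setdefault(hid, []).append(is_transfer)
        else:
            if is_transfer:
                raise ValueError("[&type=transfer] on a non-reticulation branch")
            node = new_node()
            if not has_children:
                if not name:
                    raise ValueError("unlabeled leaf")
                net.leaf_map[node] = name
        for ckind, cnode in children:
            net.add_edge(node, cnode, ckind)
        return (TRANSFER if is_transfer else SUPPORT), node

    def parse_subtree_into(acc: list) -> None:
        acc.append(parse_subtree(None))

    kind, root = parse_subtree(None)
    if kind == TRANSFER:
        raise ValueError("root branch cannot be a transfer edge")
    if peek() != ";":
        raise ValueError(f"trailing tokens after root: {peek()!r}")
    net.root = root
    for hid, tags in hybrid_occurrences.items():
        if len(tags) != 2:
            raise ValueError(f"#H{hid} appears {len(tags)} time(s); expected 2")
        if sum(tags) != 1:
            raise ValueError(
                f"#H{hid}: exactly one occurrence must carry [&type=transfer] "
                f"(saw {sum(tags)})"
            )
    if validate_result:
        violations = validate(net)
        if violations:
            raise ValueError("invalid network: " + "; ".join(violations))
    return net


def write_network(net: PhyloNetwork) -> str:
    """Serialize to the extended-Newick dialect (round-trip safe)."""
    hybrid_ids = {r: i + 1 for i, r in enumerate(sorted(v for v in net.nodes if net.is_reticulation(v)))}

    def render(v: str) -> str:
        # v is reached via its support parent; a reticulation is wrapped in
        # "(child)#Hn" so nested reticulation chains render correctly
        if net.is_reticulation(v):
            (child,) = net.children(v)
            return f"({render(child)})#H{hybrid_ids[v]}"
        if net.is_leaf(v):
            return net.leaf_map.get(v, v)
        parts = []
        for w in net.graph.successors(v):
            if net.edge_kind(v, w) == TRANSFER:
                parts.append(f"#H{hybrid_ids[w]}[&type=transfer]")
            else:
                parts.append(render(w))
        return "(" + ",".join(parts) + ")"

    if net.graph.number_of_nodes() == 1:
        return net.leaf_map.get(net.root, net.root) + ";"
    return render(net.root) + ";"


# ---------------------------------------------------------------------------
# labeling / time-map files (TSV)
# ---------------------------------------------------------------------------


def write_labeling(labeling: Mapping[str, frozenset], characters: CharacterSet) -> str:
    lines = []
    for node in sorted(labeling):
        chars = ",".join(c for c in characters if c in labeling[node])
        lines.append(f"{node}\t{chars}")
    return "\n".join(lines) + "\n"


def read_labeling(text: str) -> dict[str, frozenset]:
    labeling = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        node, _, chars = line.partition("\t")
        labeling[node] = frozenset(c for c in chars.strip().split(",") if c)
    return labeling


def write_timemap(tmap: TimeMap) -> str:
    return "\n".join(f"{v}\t{float(t)}" for v, t in sorted(tmap.tau.items())) + "\n"


def read_timemap(text: str) -> TimeMap:
    tau = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        node, _, t = line.partition("\t")
        tau[node] = float(t)
    return TimeMap(tau)


# ---------------------------------------------------------------------------
# structural validation
# ---------------------------------------------------------------------------


def validate(net: PhyloNetwork) -> list[str]:
    """Check every structural invariant; return violations (empty = valid).

    Violations are data, not exceptions: each entry names the offending
    node/edge and the broken rule.
    """
    v_list: list[str] = []
    g = net.graph
    if net.root is None or net.root not in g:
        return ["root is not set or not a node of the network"]
    n = g.number_of_nodes()
    if n == 1:
        if net.leaf_map.get(net.root) is None:
            v_list.append("single-node network: root must be mapped to a taxon")
        return v_list
    if not nx.is_directed_acyclic_graph(g):
        v_list.append("graph contains a directed cycle")
        return v_list
    if not nx.is_weakly_connected(g):
        v_list.append("graph is not connected")
    sources = [v for v in g.nodes if g.in_degree(v) == 0]
    if sources != [net.root] and set(sources) != {net.root}:
        v_list.append(f"in-degree-0 nodes {sorted(sources)} != declared root {net.root!r}")
    if g.out_degree(net.root) != 2:
        v_list.append(f"root {net.root!r} has out-degree {g.out_degree(net.root)}, expected 2")
    for v in g.nodes:
        if v == net.root:
            continue
        deg = (g.in_degree(v), g.out_degree(v))
        if deg == (1, 1):
            v_list.append(f"node {v!r} is a subdivision node (in 1 / out 1)")
        elif deg not in ((1, 0), (1, 2), (2, 1)):
            v_list.append(f"node {v!r} has degree in={deg[0]}/out={deg[1]}")
    # edge partition rules
    for (u, v) in net.transfer_edges:
        if not net.is_reticulation(v):
            v_list.append(f"transfer edge ({u!r},{v!r}) does not point into a reticulation")
    for v in g.nodes:
        if net.is_reticulation(v):
            kinds = sorted(net.edge_kind(u, v) for u in g.predecessors(v))
            if kinds != [SUPPORT, TRANSFER]:
                v_list.append(
                    f"reticulation {v!r} lacks a support+transfer parent pair (has {kinds})"
                )
    # support graph must be a spanning tree with the same leaf set
    sup = nx.DiGraph()
    sup.add_nodes_from(g.nodes)
    sup.add_edges_from(net.support_edges)
    if sup.number_of_edges() != n - 1 or not nx.is_weakly_connected(sup):
        v_list.append("support graph not a tree")
    else:
        sup_leaves = {v for v in sup.nodes if sup.out_degree(v) == 0}
        if sup_leaves != set(net.leaves):
            v_list.append(
                f"support tree leaves {sorted(sup_leaves)} != network leaves {sorted(net.leaves)}"
            )
    # sigma: total and injective on leaves
    leaves = set(net.leaves)
    mapped = set(net.leaf_map)
    if mapped != leaves:
        v_list.append(f"leaf map domain {sorted(mapped)} != leaves {sorted(leaves)}")
    names = list(net.leaf_map.values())
    if len(set(names)) != len(names):
        v_list.append("duplicate taxon names in leaf map")
    return v_list


# ---------------------------------------------------------------------------
# derived trees and graph primitives
# ---------------------------------------------------------------------------


def support_tree(net: PhyloNetwork) -> PhyloNetwork:
    """The spanning tree of support edges (may contain subdivision nodes).

    This is a *view*-style object: it is intentionally allowed to contain
    in-1/out-1 nodes and so need not pass :func:`validate` (nor must its
    input: passing a view through again is the identity).
    """
    if net.root is None or net.root not in net.graph:
        raise ValueError("invalid network: root is not set")
    tree = PhyloNetwork()
    for v in net.nodes:
        tree.add_node(v)
    for (u, v) in net.support_edges:
        tree.add_edge(u, v, SUPPORT)
    tree.root = net.root
    tree.leaf_map = dict(net.leaf_map)
    return tree


def base_tree(net: PhyloNetwork) -> PhyloNetwork:
    """Support tree with every subdivision node suppressed."""
    tree = support_tree(net)
    g = tree.graph
    for v in list(g.nodes):
        if g.in_degree(v) == 1 and g.out_degree(v) == 1:
            (p,) = g.predecessors(v)
            (c,) = g.successors(v)
            g.remove_node(v)
            g.add_edge(p, c, kind=SUPPORT)
    # a root left with a single child is also a subdivision artifact
    while tree.root in g and g.out_degree(tree.root) == 1 and g.number_of_nodes() > 1:
        (c,) = g.successors(tree.root)
        g.remove_node(tree.root)
        tree.root = c
    return tree


def reachable_set(net, v: str, kind: Optional[str] = None) -> set:
    """R_v: the set of nodes that ``v`` reaches, including ``v`` itself.

    ``net`` may be a :class:`PhyloNetwork` or a bare ``networkx.DiGraph``;
    pass ``kind`` to restrict traversal to one edge class.
    """
    g = net.graph if isinstance(net, PhyloNetwork) else net
    if v not in g:
        raise KeyError(f"unknown node {v!r}")
    seen = {v}
    stack = [v]
    while stack:
        u = stack.pop()
        for w in g.successors(u):
            if kind is not None and g.edges[u, w].get("kind") != kind:
                continue
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


def is_time_consistent(net: PhyloNetwork, tmap: TimeMap) -> bool:
    """True iff times strictly decrease along support edges and are equal
    (within tolerance) across transfer edges."""
    missing = [v for v in net.nodes if v not in tmap]
    if missing:
        raise ValueError(f"time map is partial; missing {sorted(missing)}")
    for (u, v) in net.support_edges:
        if not tmap[u] > tmap[v]:
            return False
    for (u, v) in net.transfer_edges:
        if abs(tmap[u] - tmap[v]) > TIME_TOLERANCE:
            return False
    return True


def time_consistency_feasible(net: PhyloNetwork) -> tuple[bool, Optional[TimeMap]]:
    """Decide whether *some* time-consistent map exists; return a witness.

    Each transfer edge forces time equality of its endpoints, so endpoints
    are collapsed into equality classes; support edges then induce a strict
    order between classes.  A map exists iff that class relation is acyclic,
    in which case a topological order of classes yields integer witness
    times (largest at the root side).
    """
    parent = {v: v for v in net.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (u, v) in net.transfer_edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    cls = nx.DiGraph()
    cls.add_nodes_from({find(v) for v in net.nodes})
    for (u, v) in net.support_edges:
        ru, rv = find(u), find(v)
        if ru == rv:
            return False, None  # support edge inside an equality class
        cls.add_edge(ru, rv)
    if not nx.is_directed_acyclic_graph(cls):
        return False, None
    order = list(nx.topological_sort(cls))
    n = len(order)
    class_time = {c: n - i for i, c in enumerate(order)}
    tmap = TimeMap({v: class_time[find(v)] for v in net.nodes})
    return True, tmap


def isomorphic(a: PhyloNetwork, b: PhyloNetwork) -> bool:
    """Node-relabeling isomorphism preserving sigma and the edge partition."""

    def attributed(net: PhyloNetwork) -> nx.DiGraph:
        g = nx.DiGraph()
        for v in net.nodes:
            g.add_node(v, taxon=net.leaf_map.get(v))
        for (u, v, k) in net.graph.edges(data="kind"):
            g.add_edge(u, v, kind=k)
        return g

    ga, gb = attributed(a), attributed(b)
    if ga.number_of_nodes() != gb.number_of_nodes():
        return False
    matcher = nx.algorithms.isomorphism.DiGraphMatcher(
        ga,
        gb,
        node_match=lambda x, y: x["taxon"] == y["taxon"],
        edge_match=lambda x, y: x["kind"] == y["kind"],
    )
    return matcher.is_isomorphic()


def _require_valid(net: PhyloNetwork) -> None:
    violations = validate(net)
    if violations:
        raise ValueError("invalid network: " + "; ".join(violations))
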