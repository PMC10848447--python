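"""Shared fixtures: small hand-built networks and seeded instance streams."""

import random

import pytest

from ptn import CharacterSet, PhyloNetwork, TaxaTable, network_from_edges, oracles
from ptn.netmodel import SUPPORT, TRANSFER


@pytest.fixture
def perfect_instance():
    """Taxa admitting a perfect phylogeny, on that phylogeny.

    ((A,B),(C,D)) with a on {A,B}, b on {C,D}, c on {A,B,C,D}.
    """
    chars = CharacterSet(["a", "b", "c"])
    taxa = TaxaTable(
        chars,
        {"A": {"a", "c"}, "B": {"a", "c"}, "C": {"b", "c"}, "D": {"b", "c"}},
    )
    tree = network_from_edges(
        [("r", "u"), ("r", "v"), ("u", "A"), ("u", "B"), ("v", "C"), ("v", "D")],
        {n: n for n in "ABCD"},
        root="r",
    )
    return tree, taxa


@pytest.fixture
def temporal_cycle_network():
    """Two transfers whose time-equalities contradict the support order.

    The left reticulation must be contemporaneous with a node *below* the
    right reticulation and vice versa, so no time map exists.
    """
    edges = [
        ("rho", "L1"), ("rho", "R1"),
        ("L1", "L2"), ("R1", "R2"),
        ("L2", "leafL"), ("R2", "leafR"),
        ("L2", "R1", TRANSFER), ("R2", "L1", TRANSFER),
    ]
    return network_from_edges(edges, {"leafL": "X", "leafR": "Y"}, root="rho")


def random_instance(seed):
    """Seeded small (network, taxa) pair: 2-4 leaves, 0-2 transfers,
    1-3 characters.  The network stays within the brute-force node guard."""
    rng = random.Random(seed)
    n_leaves = rng.randint(2, 4)
    n_transfers = rng.randint(0, 2)
    net = oracles.random_network(n_leaves, n_transfers, seed)
    _, taxa = oracles.random_taxa(
        n_leaves, rng.randint(1, 3), rng.choice([0.3, 0.5, 0.7]), seed + 10_000
    )
    return net, taxa


def random_tree_instance(seed, max_leaves=5, max_chars=3, density=0.5):
    """Seeded (tree, taxa) pair for completion tests."""
    rng = random.Random(seed)
    tree = oracles.random_tree(rng.randint(3, max_leaves), seed + 1)
    _, taxa = oracles.random_taxa(
        len(tree.leaves), rng.randint(2, max_chars), density, seed + 2
    )
    return tree, taxa


def path_of_cherries(n_cherries):
    """Caterpillar whose spine hangs a cherry at every node (quadratic-
    runtime probe for recognition)."""
    edges = []
    leaf_map = {}
    for i in range(n_cherries):
        spine, cherry = f"s{i}", f"ch{i}"
        a, b = f"x{i}", f"y{i}"
        edges += [(spine, cherry), (cherry, a), (cherry, b)]
        leaf_map[a] = a
        leaf_map[b] = b
        if i + 1 < n_cherries:
            edges.append((spine, f"s{i + 1}"))
        else:
            edges.append((spine, f"tail{i}"))
            leaf_map[f"tail{i}"] = f"tail{i}"
    return network_from_edges(edges, leaf_map, root="s0")


def small_network_family():
    """Every tree-based network with at most 8 nodes, up to symmetry.

    Binary networks have 2L-1+2T nodes (L leaves, T transfers), so the
    possibilities are: the single node, trees with 2-4 leaves (one 3-leaf
    and two 4-leaf shapes), and the cherry with one transfer in either
    direction (5 nodes); a 3-leaf tree plus a transfer already has 9.
    """
    single = PhyloNetwork()
    single.add_node("A")
    single.root = "A"
    single.leaf_map = {"A": "A"}
    cherry = network_from_edges([("r", "A"), ("r", "B")], {"A": "A", "B": "B"}, root="r")
    three = network_from_edges(
        [("r", "u"), ("r", "C"), ("u", "A"), ("u", "B")], {n: n for n in "ABC"}, root="r"
    )
    balanced = network_from_edges(
        [("r", "u"), ("r", "v"), ("u", "A"), ("u", "B"), ("v", "C"), ("v", "D")],
        {n: n for n in "ABCD"},
        root="r",
    )
    caterpillar = network_from_edges(
        [("r", "u"), ("r", "D"), ("u", "v"), ("u", "C"), ("v", "A"), ("v", "B")],
        {n: n for n in "ABCD"},
        root="r",
    )
    nets = [single, cherry, three, balanced, caterpillar]
    for donor_child, recip_child in (("A", "B"), ("B", "A")):
        net = network_from_edges(
            [
                ("r", "dw"), ("r", "ret"),
                ("dw", donor_child), ("dw", "ret", TRANSFER),
                ("ret", recip_child),
            ],
            {"A": "A", "B": "B"},
            root="r",
        )
        nets.append(net)
    return nets


def all_labelings(net, chars):
    """Every assignment of character subsets to the network's nodes."""
    import itertools

    nodes = sorted(net.nodes)
    subsets = [frozenset(s) for r in range(len(chars) + 1) for s in itertools.combinations(chars, r)]
    for combo in itertools.product(subsets, repeat=len(nodes)):
        yield dict(zip(nodes, combo))
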