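"""Containers, file formats, validation, and graph primitives."""

import itertools
import random

import numpy as np
import pytest

from ptn import (
    CharacterSet,
    PhyloNetwork,
    TaxaTable,
    base_tree,
    completion,
    is_time_consistent,
    isomorphic,
    network_from_edges,
    oracles,
    parse_network,
    reachable_set,
    read_character_matrix,
    support_tree,
    time_consistency_feasible,
    validate,
    worstcase,
    write_character_matrix,
    write_network,
)
from ptn.netmodel import SUPPORT, TRANSFER, TimeMap, write_labeling, read_labeling

from conftest import random_instance


# ---------------------------------------------------------------------------
# character matrix
# ---------------------------------------------------------------------------


class TestCharacterMatrix:
    def test_direct_decoding(self):
        chars, taxa = read_character_matrix("taxon,a,b\nA,1,0\nB,1,1\n")
        assert list(chars) == ["a", "b"]
        assert taxa["A"] == {"a"} and taxa["B"] == {"a", "b"}

    def test_tsv_sniffing(self):
        chars, taxa = read_character_matrix("taxon\ta\tb\nA\t0\t1\n")
        assert taxa["A"] == {"b"}

    def test_empty_subset_accepted(self):
        _, taxa = read_character_matrix("taxon,a\nA,0\n")
        assert taxa["A"] == frozenset()

    @pytest.mark.parametrize(
        "text",
        [
            "taxon,a\nA,2\n",           # cell outside {0,1}
            "taxon,a\nA,1\nA,0\n",      # duplicate taxon
            "taxon,a,b\nA,1\n",         # ragged row
        ],
    )
    def test_malformed_matrices_rejected(self, text):
        with pytest.raises(ValueError):
            read_character_matrix(text)

    def test_duplicate_characters_rejected(self):
        with pytest.raises(ValueError):
            read_character_matrix("taxon,a,a\nA,1,0\n")

    def test_roundtrip(self):
        _, taxa = oracles.random_taxa(6, 4, 0.4, 11)
        chars2, taxa2 = read_character_matrix(write_character_matrix(taxa))
        assert dict(taxa2) == dict(taxa)
        assert list(chars2) == list(taxa.characters)

    def test_character_set_invariants(self):
        with pytest.raises(ValueError):
            CharacterSet(["a", "a"])
        with pytest.raises(ValueError):
            CharacterSet([""])
        with pytest.raises(ValueError):
            TaxaTable(CharacterSet(["a"]), {"A": {"zzz"}})


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------


class TestNewick:
    def test_plain_tree(self):
        net = parse_network("((A,B),C);")
        assert len(net.leaves) == 3
        assert net.transfer_edges == []
        assert validate(net) == []

    def test_single_reticulation(self):
        net = parse_network("((A,(X)#H1),(B,#H1[&type=transfer]));")
        assert sum(net.is_reticulation(v) for v in net.nodes) == 1
        assert len(net.transfer_edges) == 1
        assert validate(net) == []

    def test_missing_transfer_tag_is_ambiguous(self):
        with pytest.raises(ValueError, match="type=transfer"):
            parse_network("((A,(X)#H1),(B,#H1));")

    def test_hybrid_label_must_appear_twice(self):
        with pytest.raises(ValueError, match="#H1 appears"):
            parse_network("((A,(X)#H1),B);")

    def test_single_node(self):
        net = parse_network("A;")
        assert net.leaves == [net.root]
        assert write_network(net) == "A;"

    @pytest.mark.parametrize("seed", range(6))
    def test_roundtrip_random_networks(self, seed):
        net, _ = random_instance(seed)
        again = parse_network(write_network(net))
        assert isomorphic(net, again)

    def test_roundtrip_completion_output(self):
        tree = oracles.random_tree(5, 3)
        _, taxa = oracles.random_taxa(5, 3, 0.5, 4)
        res = completion.complete(tree, taxa)
        again = parse_network(write_network(res.network))
        assert isomorphic(res.network, again)

    def test_roundtrip_worstcase(self):
        net = worstcase.worstcase_ptn(2)
        again = parse_network(write_network(net))
        assert isomorphic(net, again)
        assert len(again.leaves) == 4

    def test_plain_newick_for_trees(self):
        tree = oracles.random_tree(4, 0)
        text = write_network(tree)
        assert "#H" not in text


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


class TestValidate:
    def test_tree_is_valid(self):
        assert validate(oracles.random_tree(5, 1)) == []

    def test_subdivision_node_rejected(self):
        net = network_from_edges(
            [("r", "s"), ("r", "B"), ("s", "A")], {"A": "A", "B": "B"}, root="r"
        )
        assert any("subdivision" in v for v in validate(net))

    def test_directed_cycle_reported(self):
        net = PhyloNetwork()
        for v in ("r", "u", "v", "A", "B"):
            net.add_node(v)
        net.root = "r"
        net.add_edge("r", "u")
        net.add_edge("r", "A")
        net.add_edge("u", "v")
        net.add_edge("v", "B")
        net.add_edge("v", "u", TRANSFER)  # closes the directed cycle u -> v -> u
        net.leaf_map = {"A": "A", "B": "B"}
        assert any("cycle" in msg for msg in validate(net))

    def test_support_edges_must_form_tree(self):
        net = network_from_edges(
            [
                ("r", "u"), ("r", "v"),
                ("u", "A"), ("u", "x", SUPPORT),
                ("v", "B"), ("v", "x", SUPPORT),
                ("x", "C"),
            ],
            {"A": "A", "B": "B", "C": "C"},
            root="r",
        )
        assert any("support graph not a tree" in msg for msg in validate(net))

    def test_reticulation_needs_transfer_parent(self):
        # reticulation with two incoming support edges
        net = network_from_edges(
            [
                ("r", "u"), ("r", "ret"),
                ("u", "A"), ("u", "ret", SUPPORT),
                ("ret", "B"),
            ],
            {"A": "A", "B": "B"},
            root="r",
        )
        msgs = " ".join(validate(net))
        assert "support+transfer" in msgs or "support graph not a tree" in msgs

    def test_leaf_map_mismatch(self):
        net = network_from_edges([("r", "A"), ("r", "B")], {"A": "A"}, root="r")
        assert any("leaf map" in v for v in validate(net))


# ---------------------------------------------------------------------------
# support / base trees
# ---------------------------------------------------------------------------


class TestDerivedTrees:
    def test_identity_on_trees(self):
        tree = oracles.random_tree(5, 2)
        assert isomorphic(support_tree(tree), tree)
        assert isomorphic(base_tree(tree), tree)

    def test_subdivision_count_is_twice_transfers(self):
        net = worstcase.worstcase_ptn(3)
        sup = support_tree(net)
        subdiv = [
            v
            for v in sup.nodes
            if sup.graph.in_degree(v) == 1 and sup.graph.out_degree(v) == 1
        ]
        assert len(subdiv) == 2 * len(net.transfer_edges)

    def test_base_of_support_is_base(self):
        for seed in range(4):
            net, _ = random_instance(seed + 50)
            assert isomorphic(base_tree(support_tree(net)), base_tree(net))

    def test_completion_base_tree_is_input(self):
        tree = oracles.random_tree(6, 9)
        _, taxa = oracles.random_taxa(6, 2, 0.5, 10)
        res = completion.complete(tree, taxa)
        bt = base_tree(res.network)
        assert isomorphic(bt, tree)
        # identical sigma, node for node
        assert bt.leaf_map == tree.leaf_map


# ---------------------------------------------------------------------------
# reachability
# ---------------------------------------------------------------------------


class TestReachability:
    def test_leaf_reaches_only_itself(self):
        tree = oracles.random_tree(4, 3)
        leaf = tree.leaves[0]
        assert reachable_set(tree, leaf) == {leaf}

    def test_root_reaches_everything(self):
        tree = oracles.random_tree(4, 4)
        assert reachable_set(tree, tree.root) == set(tree.nodes)

    def test_unknown_node(self):
        with pytest.raises(KeyError):
            reachable_set(oracles.random_tree(3, 5), "nope")

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_matrix_power_closure(self, seed):
        net, _ = random_instance(seed + 300)
        nodes = sorted(net.nodes)
        idx = {v: i for i, v in enumerate(nodes)}
        n = len(nodes)
        adj = np.eye(n, dtype=bool)
        for (u, v) in net.graph.edges:
            adj[idx[u], idx[v]] = True
        closure = adj.copy()
        for _ in range(n):
            closure = closure @ adj | closure
        for v in nodes:
            expected = {nodes[j] for j in range(n) if closure[idx[v], j]}
            assert reachable_set(net, v) == expected


# ---------------------------------------------------------------------------
# time consistency
# ---------------------------------------------------------------------------


class TestTimeConsistency:
    def test_height_map_on_tree(self):
        tree = oracles.random_tree(5, 6)
        assert is_time_consistent(tree, completion.initial_time_map(tree))

    def test_unequal_transfer_times_rejected(self):
        net, _ = _one_transfer_network()
        ok, tmap = time_consistency_feasible(net)
        assert ok and is_time_consistent(net, tmap)
        (u, v) = net.transfer_edges[0]
        tmap[u] = tmap[u] + 1
        assert not is_time_consistent(net, tmap)

    def test_partial_map_rejected(self):
        tree = oracles.random_tree(3, 7)
        with pytest.raises(ValueError):
            is_time_consistent(tree, TimeMap({tree.root: 1.0}))

    def test_temporal_cycle_infeasible(self, temporal_cycle_network):
        ok, tmap = time_consistency_feasible(temporal_cycle_network)
        assert not ok and tmap is None

    def test_temporal_cycle_verified_by_exhaustive_search(self, temporal_cycle_network):
        """No assignment of distinct class times satisfies the constraints:
        exhaustive search over orderings of the equality classes."""
        net = temporal_cycle_network
        # merge transfer endpoints into classes
        classes = {v: v for v in net.nodes}
        for (u, v) in net.transfer_edges:
            target = classes[v]
            classes = {x: (target if c == classes[u] else c) for x, c in classes.items()}
        ids = sorted(set(classes.values()))
        found = False
        for perm in itertools.permutations(range(len(ids))):
            t = dict(zip(ids, perm))
            if all(t[classes[u]] > t[classes[v]] for (u, v) in net.support_edges):
                found = True
                break
        assert not found

    def test_completions_are_feasible(self):
        for seed in range(5):
            tree = oracles.random_tree(5, seed)
            _, taxa = oracles.random_taxa(5, 3, 0.5, seed + 40)
            net = completion.complete(tree, taxa).network
            ok, tmap = time_consistency_feasible(net)
            assert ok and is_time_consistent(net, tmap)


def _one_transfer_network():
    net = network_from_edges(
        [
            ("r", "dw"), ("r", "ret"),
            ("dw", "A"), ("dw", "ret", TRANSFER),
            ("ret", "B"),
        ],
        {"A": "A", "B": "B"},
        root="r",
    )
    return net, None


# ---------------------------------------------------------------------------
# labeling files
# ---------------------------------------------------------------------------


def test_labeling_file_roundtrip():
    chars = CharacterSet(["a", "b"])
    lab = {"n1": frozenset({"a"}), "n2": frozenset(), "n3": frozenset({"a", "b"})}
    assert read_labeling(write_labeling(lab, chars)) == lab
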