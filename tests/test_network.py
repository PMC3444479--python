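"""Network construction, loop counting, and branch partitions vs brute force."""

import itertools

import networkx as nx
import pytest

from mitoscan.network import (
    build_network,
    enumerate_partitions,
    export_edge_tsv,
    export_graphml,
    loop_count,
    step_distance,
)
from mitoscan.variants import SNV, Variant

from conftest import make_haplotypes


def v(pos):
    return Variant(pos, SNV, "A", "G")


class TestStepDistance:
    def test_zero_iff_equal(self):
        a = frozenset({v(1), v(2)})
        assert step_distance(a, a) == 0

    def test_subset_and_disjoint(self):
        assert step_distance(frozenset({v(263)}), frozenset({v(263), v(750)})) == 1
        assert step_distance(frozenset({v(263)}), frozenset({v(750)})) == 2

    def test_symmetry(self):
        a, b = frozenset({v(1), v(3)}), frozenset({v(2)})
        assert step_distance(a, b) == step_distance(b, a) == 3


def observed_topology(net):
    """Edges of the network with inferred degree-2 chains contracted."""
    g = net.graph.copy()
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if not g.nodes[n]["observed"] and g.degree[n] == 2:
                a, b = list(g.neighbors(n))
                g.remove_node(n)
                g.add_edge(a, b)
                changed = True
    return g


def union_of_msts(haplotypes):
    """Independent oracle: union of all MSTs of the complete step-distance graph."""
    g = nx.Graph()
    for a, b in itertools.combinations(haplotypes, 2):
        g.add_edge(a.id, b.id, weight=step_distance(a, b))
    msts = []
    best = None
    nodes = [h.id for h in haplotypes]
    edges = list(g.edges(data="weight"))
    for subset in itertools.combinations(range(len(edges)), len(nodes) - 1):
        t = nx.Graph()
        t.add_nodes_from(nodes)
        t.add_edges_from((edges[i][0], edges[i][1]) for i in subset)
        if not nx.is_connected(t):
            continue
        w = sum(edges[i][2] for i in subset)
        if best is None or w < best:
            best = w
            msts = [t]
        elif w == best:
            msts.append(t)
    out = nx.Graph()
    out.add_nodes_from(nodes)
    for t in msts:
        out.add_edges_from(t.edges)
    return out


class TestBuildNetwork:
    def test_path_of_three(self):
        haps = make_haplotypes({
            "A": frozenset(), "B": frozenset({v(1)}), "C": frozenset({v(1), v(2)}),
        })
        net = build_network(haps)
        assert sorted(map(sorted, net.graph.edges)) == [["A", "B"], ["B", "C"]]
        assert loop_count(net) == 0

    def test_distance_three_pair_gets_two_intermediates(self):
        haps = make_haplotypes({"A": frozenset(), "B": frozenset({v(1), v(2), v(3)})})
        net = build_network(haps)
        assert net.graph.number_of_nodes() == 4
        assert net.graph.number_of_edges() == 3
        inferred = [n for n, d in net.graph.nodes(data=True) if not d["observed"]]
        assert len(inferred) == 2
        assert all(net.graph.degree[n] == 2 for n in inferred)
        # every edge differs by exactly its labelled variant
        for a, b, data in net.graph.edges(data=True):
            assert net.variant_sets[a] ^ net.variant_sets[b] == {data["variant"]}

    def test_four_cycle_of_equal_alternatives_retained(self):
        haps = make_haplotypes({
            "R": frozenset(), "X": frozenset({v(1)}),
            "Y": frozenset({v(2)}), "XY": frozenset({v(1), v(2)}),
        })
        net = build_network(haps)
        assert loop_count(net) == 1
        assert net.graph.number_of_edges() == 4
        oracle = union_of_msts(haps)
        assert set(map(frozenset, observed_topology(net).edges)) == set(
            map(frozenset, oracle.edges)
        )

    def test_tied_chains_meet_at_shared_ancestral_intermediate(self):
        # three haplotypes one private variant each: all pairwise chains pass
        # through the inferred ancestral state (the empty set), giving a star
        # rather than a triangle of parallel routes
        haps = make_haplotypes({
            "A": frozenset({v(1)}), "B": frozenset({v(2)}), "C": frozenset({v(3)}),
        })
        net = build_network(haps)
        assert net.graph.number_of_nodes() == 4
        assert net.graph.number_of_edges() == 3
        assert loop_count(net) == 0
        hub = next(n for n, d in net.graph.nodes(data=True) if not d["observed"])
        assert net.variant_sets[hub] == frozenset()

    def test_input_order_invariance(self):
        haps = make_haplotypes({
            "A": frozenset(), "B": frozenset({v(1)}), "C": frozenset({v(2), v(3)}),
            "D": frozenset({v(2)}),
        })
        nets = [build_network(list(order)) for order in itertools.permutations(haps)]
        edge_sets = {frozenset(map(frozenset, n.graph.edges)) for n in nets}
        assert len(edge_sets) == 1

    def test_max_steps_cap_leaves_components_apart(self):
        haps = make_haplotypes({"A": frozenset(), "B": frozenset({v(1), v(2), v(3)})})
        net = build_network(haps, max_steps=2)
        assert nx.number_connected_components(net.graph) == 2


class TestLoopCount:
    def test_tree_has_zero(self):
        haps = make_haplotypes({"A": frozenset(), "B": frozenset({v(1)})})
        assert loop_count(build_network(haps)) == 0

    def test_two_squares_sharing_one_edge(self):
        haps = make_haplotypes({
            "R": frozenset(), "A": frozenset({v(1)}), "B": frozenset({v(2)}),
            "AB": frozenset({v(1), v(2)}), "C": frozenset({v(3)}),
            "AC": frozenset({v(1), v(3)}),
        })
        net = build_network(haps)
        assert (net.graph.number_of_nodes(), net.graph.number_of_edges()) == (6, 7)
        assert loop_count(net) == 2


def brute_force_partitions(net):
    """Oracle: every spanning tree, every edge removal, flood observed sides."""
    out = set()
    for comp in nx.connected_components(net.graph):
        sub = net.graph.subgraph(comp)
        observed = {n for n in comp if net.graph.nodes[n]["observed"]}
        if len(observed) < 2:
            continue
        edges = list(sub.edges)
        n_nodes = len(comp)
        for subset in itertools.combinations(range(len(edges)), n_nodes - 1):
            t = nx.Graph()
            t.add_nodes_from(comp)
            t.add_edges_from(edges[i] for i in subset)
            if not nx.is_connected(t):
                continue
            for e in t.edges:
                t2 = t.copy()
                t2.remove_edge(*e)
                sides = [set(c) & observed for c in nx.connected_components(t2)]
                sides = [frozenset(s) for s in sides if s]
                if len(sides) == 2:
                    out.add(frozenset(sides))
    return out


class TestEnumeratePartitions:
    def test_path_of_three_observed(self):
        haps = make_haplotypes({
            "A": frozenset(), "B": frozenset({v(1)}), "C": frozenset({v(1), v(2)}),
        })
        net = build_network(haps)
        parts = enumerate_partitions(net)
        keys = {p.sides_key() for p in parts}
        assert keys == {
            frozenset({frozenset({"A"}), frozenset({"B", "C"})}),
            frozenset({frozenset({"A", "B"}), frozenset({"C"})}),
        }

    def test_star_isolates_each_leaf(self):
        haps = make_haplotypes(
            {"C": frozenset(), "L1": frozenset({v(1)}), "L2": frozenset({v(2)}),
             "L3": frozenset({v(3)})},
            counts={"C": 5, "L1": 1, "L2": 1, "L3": 1},
        )
        net = build_network(haps)
        parts = enumerate_partitions(net)
        assert len(parts) == 3
        assert all(len(p.side_b) == 1 for p in parts)  # minor side is the leaf

    def test_multi_segment_branch_lists_all_variants(self):
        haps = make_haplotypes({"A": frozenset(), "B": frozenset({v(1), v(2)})})
        net = build_network(haps)
        parts = enumerate_partitions(net)
        assert len(parts) == 1
        assert {x.position for x in parts[0].defining_variants} == {1, 2}

    @pytest.mark.parametrize("fixture", ["four_cycle", "two_squares", "cycle_with_tail"])
    def test_matches_brute_force_on_loopy_fixtures(self, fixture):
        sets = {
            "four_cycle": {
                "R": frozenset(), "X": frozenset({v(1)}), "Y": frozenset({v(2)}),
                "XY": frozenset({v(1), v(2)}),
            },
            "two_squares": {
                "R": frozenset(), "A": frozenset({v(1)}), "B": frozenset({v(2)}),
                "AB": frozenset({v(1), v(2)}), "C": frozenset({v(3)}),
                "AC": frozenset({v(1), v(3)}),
            },
            "cycle_with_tail": {
                "R": frozenset(), "X": frozenset({v(1)}), "Y": frozenset({v(2)}),
                "XY": frozenset({v(1), v(2)}), "T": frozenset({v(1), v(2), v(3)}),
            },
        }[fixture]
        net = build_network(make_haplotypes(sets))
        got = {p.sides_key() for p in enumerate_partitions(net)}
        assert got == brute_force_partitions(net)

    def test_resolution_support_counts_on_four_cycle(self):
        haps = make_haplotypes({
            "R": frozenset(), "X": frozenset({v(1)}), "Y": frozenset({v(2)}),
            "XY": frozenset({v(1), v(2)}),
        })
        parts = enumerate_partitions(build_network(haps))
        # 4 spanning trees (drop one cycle edge each): every path endpoint
        # yields a singleton split (each node is an endpoint in 2 trees) and
        # the two distinct middle splits each also arise in 2 trees
        assert len(parts) == 6
        assert all(p.n_resolutions == 2 for p in parts)

    def test_nesting_property_sides_subset_ordered(self):
        haps = make_haplotypes({
            "A": frozenset(), "B": frozenset({v(1)}), "C": frozenset({v(1), v(2)}),
            "D": frozenset({v(1), v(2), v(3)}),
        }, counts={"A": 10, "B": 2, "C": 1, "D": 1})
        parts = enumerate_partitions(build_network(haps))
        clades = sorted((p.side_b for p in parts), key=len)
        for small, big in itertools.combinations(clades, 2):
            if small & big:
                assert small <= big or big <= small


def test_exports(tmp_path):
    haps = make_haplotypes({"A": frozenset(), "B": frozenset({v(1), v(2)})})
    net = build_network(haps)
    export_graphml(net, tmp_path / "n.graphml")
    export_edge_tsv(net, tmp_path / "n.tsv")
    back = nx.read_graphml(tmp_path / "n.graphml")
    assert back.number_of_nodes() == 3
    lines = (tmp_path / "n.tsv").read_text().strip().splitlines()
    assert lines[0] == "node_a\tnode_b\tvariant"
    assert len(lines) == 3
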