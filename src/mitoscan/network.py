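"""Haplotype network construction and branch partitions.

The network is a graph over haplotypes in which every edge represents exactly
one mutational step (one variant). Haplotype pairs more than one step apart
are joined through inferred, unsampled intermediate nodes. Connections are
added in nondecreasing step-distance order, and *all* alternative connections
of equal minimal length are retained, which can create cycles (reticulations
/ "loops") exactly where the data are ambiguous about the mutational route.
Formally the observed-node topology is the union of all minimum spanning
trees under the step metric, with long edges subdivided by intermediates.

Each branch of a tree-resolved network splits the observed haplotypes into
two clades (a bi-allelic partition), the unit tested by the association scan.
Components with cycles are resolved into every spanning tree; the distinct
partitions are deduplicated and each records how many resolutions support it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import networkx as nx

from .variants import Haplotype, Variant


def step_distance(a: Union[Haplotype, frozenset], b: Union[Haplotype, frozenset]) -> int:
    """Mutational steps between two haplotypes: |symmetric difference|.

    Each indel counts as one step. Symmetric, zero iff the sets are equal.
    """
    sa = a.variants if isinstance(a, Haplotype) else frozenset(a)
    sb = b.variants if isinstance(b, Haplotype) else frozenset(b)
    return len(sa ^ sb)


class HaplotypeNetwork:
    """Graph over observed + inferred haplotypes, one variant per edge."""

    def __init__(
        self,
        graph: nx.Graph,
        variant_sets: dict[str, frozenset[Variant]],
        haplotypes: dict[str, Haplotype],
    ) -> None:
        self.graph = graph
        self.variant_sets = variant_sets
        self.haplotypes = haplotypes  # observed only

    def observed_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["observed"])

    def components(self) -> list[set[str]]:
        return sorted(nx.connected_components(self.graph), key=lambda c: min(c))

    def carrier_count(self, node: str) -> int:
        return self.graph.nodes[node]["carrier_count"]


class _UnionFind:
    def __init__(self, items: Iterable[str]) -> None:
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _variant_sort_key(v: Variant) -> tuple:
    return (v.position, v.kind, v.alt_allele, v.ref_allele)


def build_network(
    haplotypes: Sequence[Haplotype],
    max_steps: Optional[int] = None,
) -> HaplotypeNetwork:
    """Build the minimum-length haplotype network.

    Pairs are connected in nondecreasing step-distance order; a pair at
    distance d is admitted whenever its endpoints were in different connected
    components before any distance-d connection was made (the union-of-all-
    minimum-spanning-trees rule, which retains equally parsimonious
    alternatives as loops). A pair at distance d > 1 is joined through d - 1
    inferred intermediates, applying the differing variants in ascending
    position order. No connection longer than ``max_steps`` is created;
    unconnectable haplotypes remain separate components. Deterministic and
    invariant to the input order of haplotypes.
    """
    if not haplotypes:
        raise ValueError("at least one haplotype required")
    haps = sorted(haplotypes, key=lambda h: h.id)
    if len({h.id for h in haps}) != len(haps):
        raise ValueError("duplicate haplotype ids")

    graph = nx.Graph()
    variant_sets: dict[str, frozenset[Variant]] = {}
    set_to_node: dict[frozenset[Variant], str] = {}
    for h in haps:
        graph.add_node(h.id, observed=True, carrier_count=h.carrier_count, haplotype=h.id)
        variant_sets[h.id] = frozenset(h.variants)
        if frozenset(h.variants) in set_to_node:
            raise ValueError(f"haplotypes {set_to_node[frozenset(h.variants)]} and {h.id} "
                             "have identical variant sets")
        set_to_node[frozenset(h.variants)] = h.id

    def node_key(hid: str) -> tuple:
        return (-graph.nodes[hid]["carrier_count"], hid)

    pair_dist: dict[int, list[tuple[str, str]]] = {}
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            d = step_distance(haps[i], haps[j])
            if max_steps is not None and d > max_steps:
                continue
            a, b = sorted((haps[i].id, haps[j].id), key=node_key)
            pair_dist.setdefault(d, []).append((a, b))

    uf = _UnionFind([h.id for h in haps])
    inferred_count = 0

    # variant carrier frequency among observed haplotypes: a proxy for
    # mutation age (on homoplasy-free data, rarer = younger = lower in the
    # genealogy), used to route inferred chains through real ancestral states
    freq: dict[Variant, int] = {}
    for h in haps:
        for v in h.variants:
            freq[v] = freq.get(v, 0) + 1

    def _chain_key(v: Variant) -> tuple:
        return (freq.get(v, 0), *_variant_sort_key(v))

    def add_connection(a: str, b: str) -> None:
        # route through the shared variant set a∩b: strip a-private variants
        # youngest-first (walking up toward the common ancestor), then add
        # b-private variants oldest-first (walking down to b). On
        # homoplasy-free data the intermediates are ancestral haplotypes, so
        # chains from different pairs meet at shared nodes instead of
        # spawning spurious parallel routes
        nonlocal inferred_count
        diff = sorted(variant_sets[a] - variant_sets[b], key=_chain_key) + sorted(
            variant_sets[b] - variant_sets[a], key=_chain_key, reverse=True
        )
        cur_set, cur_node = variant_sets[a], a
        for var in diff:
            nxt_set = cur_set ^ {var}
            if nxt_set == variant_sets[b]:
                nxt_node = b
            elif nxt_set in set_to_node:
                nxt_node = set_to_node[nxt_set]
            else:
                inferred_count += 1
                nxt_node = f"I{inferred_count:04d}"
                graph.add_node(nxt_node, observed=False, carrier_count=0, haplotype="")
                variant_sets[nxt_node] = nxt_set
                set_to_node[nxt_set] = nxt_node
            graph.add_edge(cur_node, nxt_node, variant=var)
            cur_set, cur_node = nxt_set, nxt_node

    for d in sorted(pair_dist):
        tier = [(a, b) for a, b in pair_dist[d] if uf.find(a) != uf.find(b)]
        tier.sort(key=lambda ab: (node_key(ab[0]), node_key(ab[1])))
        for a, b in tier:
            add_connection(a, b)
        for a, b in tier:
            uf.union(a, b)

    return HaplotypeNetwork(graph, variant_sets, {h.id: h for h in haps})


def loop_count(network: HaplotypeNetwork) -> int:
    """Cycle-space dimension E - V + C (0 for forests)."""
    g = network.graph
    return g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)


@dataclass(frozen=True)
class BranchPartition:
    """Bi-allelic split of a component's observed haplotypes at one branch.

    ``side_b`` is the minor side (fewer carriers; the "clade" reported for a
    hit), ``side_a`` the rest of the component. ``defining_variants`` lists
    the variant of every segment of the branch (a branch through inferred
    degree-2 nodes has several segments, hence several defining variants).
    ``n_resolutions`` counts the spanning-tree resolutions of the component
    that produce this partition (1 for acyclic components).
    """

    branch_id: str
    component: int
    side_a: frozenset[str]
    side_b: frozenset[str]
    defining_variants: tuple[Variant, ...]
    resolution_id: int = 0
    n_resolutions: int = 1

    def sides_key(self) -> frozenset:
        return frozenset((self.side_a, self.side_b))


def _tree_partitions(
    tree: nx.Graph, observed: list[str]
) -> dict[frozenset, list]:
    """Map partition key -> [below-set, variants, edges] for one resolved tree."""
    all_observed = frozenset(observed)
    root = observed[0]
    parent: dict[str, Optional[str]] = {root: None}
    order: list[str] = []
    stack = [root]
    while stack:
        u = stack.pop()
        order.append(u)
        for w in tree.neighbors(u):
            if w not in parent:
                parent[w] = u
                stack.append(w)
    below: dict[str, set[str]] = {u: set() for u in parent}
    for u in reversed(order):
        if tree.nodes[u]["observed"]:
            below[u].add(u)
        if parent[u] is not None:
            below[parent[u]] |= below[u]
    groups: dict[frozenset, list] = {}
    for u in order:
        p = parent[u]
        if p is None:
            continue
        side = frozenset(below[u])
        other = all_observed - side
        if not side or not other:
            continue  # dangling inferred subtree: no observed split
        key = frozenset((side, other))
        rec = groups.setdefault(key, [side, [], []])
        rec[1].append(tree.edges[p, u]["variant"])
        rec[2].append((p, u))
    return groups


def enumerate_partitions(
    network: HaplotypeNetwork, max_spanning_trees: int = 10000
) -> list[BranchPartition]:
    """All distinct branch partitions across spanning-tree resolutions.

    Acyclic components contribute one partition per branch (maximal chain of
    edges through inferred degree-2 nodes). Components with loops are resolved
    into each spanning tree (up to ``max_spanning_trees``); the distinct
    partitions are deduplicated by their two sides.
    """
    carriers = {n: network.graph.nodes[n]["carrier_count"] for n in network.graph}
    results: list[BranchPartition] = []
    for comp_idx, comp in enumerate(network.components()):
        observed = sorted(n for n in comp if network.graph.nodes[n]["observed"])
        if len(observed) < 2:
            continue
        sub = network.graph.subgraph(comp)
        acyclic = sub.number_of_edges() == len(comp) - 1
        if acyclic:
            trees: Iterable[nx.Graph] = [sub]
        else:
            weighted = nx.Graph()
            weighted.add_nodes_from(sub.nodes(data=True))
            weighted.add_edges_from((u, v, {**d, "weight": 1}) for u, v, d in sub.edges(data=True))
            trees = nx.SpanningTreeIterator(weighted)
        seen: dict[frozenset, dict] = {}
        for res_id, tree in enumerate(trees):
            if res_id >= max_spanning_trees:
                break
            for key, (side, variants, edges) in _tree_partitions(tree, observed).items():
                if key in seen:
                    seen[key]["support"] += 1
                else:
                    seen[key] = {
                        "side": side,
                        "variants": tuple(sorted(variants, key=_variant_sort_key)),
                        "resolution": res_id,
                        "support": 1,
                    }
        comp_parts = []
        for key, rec in seen.items():
            side = rec["side"]
            other = frozenset(s for pair in key for s in pair) - side
            ca = sum(carriers[n] for n in side)
            cb = sum(carriers[n] for n in other)
            # side_b = minor ("clade") side
            if (cb, len(other), tuple(sorted(other))) <= (ca, len(side), tuple(sorted(side))):
                side_a, side_b = side, other
            else:
                side_a, side_b = other, side
            comp_parts.append((side_a, side_b, rec))
        comp_parts.sort(
            key=lambda t: (
                sum(carriers[n] for n in t[1]),
                len(t[1]),
                tuple(sorted(t[1])),
            )
        )
        for side_a, side_b, rec in comp_parts:
            results.append(
                BranchPartition(
                    branch_id="",
                    component=comp_idx,
                    side_a=side_a,
                    side_b=side_b,
                    defining_variants=rec["variants"],
                    resolution_id=rec["resolution"],
                    n_resolutions=rec["support"],
                )
            )
    return [
        BranchPartition(
            branch_id=f"b{i + 1:04d}",
            component=p.component,
            side_a=p.side_a,
            side_b=p.side_b,
            defining_variants=p.defining_variants,
            resolution_id=p.resolution_id,
            n_resolutions=p.n_resolutions,
        )
        for i, p in enumerate(results)
    ]


def export_graphml(network: HaplotypeNetwork, path: Union[str, Path]) -> None:
    """Write the network as GraphML (variant tokens as edge attributes)."""
    g = nx.Graph()
    for n, d in network.graph.nodes(data=True):
        g.add_node(n, observed=bool(d["observed"]), carrier_count=int(d["carrier_count"]),
                   haplotype=str(d.get("haplotype", "")))
    for u, v, d in network.graph.edges(data=True):
        g.add_edge(u, v, variant=d["variant"].token())
    nx.write_graphml(g, str(path))


def export_edge_tsv(network: HaplotypeNetwork, path: Union[str, Path]) -> None:
    """Plain TSV edge list: node_a, node_b, variant token."""
    rows = sorted(
        (min(u, v), max(u, v), d["variant"].token())
        for u, v, d in network.graph.edges(data=True)
    )
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tvariant\n")
        for u, v, t in rows:
            fh.write(f"{u}\t{v}\t{t}\n")
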