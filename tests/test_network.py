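import itertools

import networkx as nx
import numpy as np
import pytest

from phylospread import (
    DistanceMatrix,
    PopulationRow,
    SampleTable,
    build_msn,
    infer_ancestor,
    insert_missing,
    nest_clades,
    resolve_loops,
    split_lineages,
    suppress_latent,
)


def dm(labels, entries):
    """Build a mutation-step matrix from {(a,b): steps}."""
    n = len(labels)
    v = np.zeros((n, n))
    idx = {l: i for i, l in enumerate(labels)}
    for (a, b), w in entries.items():
        v[idx[a], idx[b]] = v[idx[b], idx[a]] = w
    return DistanceMatrix(tuple(labels), v, "mutation-steps")


def oracle_msn_edges(steps: DistanceMatrix) -> set:
    """Union of all minimum-weight spanning trees, by exhaustive enumeration."""
    labels = steps.labels
    n = len(labels)
    all_edges = [
        (labels[i], labels[j], steps.values[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    ]
    best = None
    trees = []
    for combo in itertools.combinations(all_edges, n - 1):
        g = nx.Graph()
        g.add_nodes_from(labels)
        g.add_weighted_edges_from(combo)
        if not nx.is_connected(g):
            continue
        w = sum(e[2] for e in combo)
        if best is None or w < best - 1e-9:
            best = w
            trees = [combo]
        elif abs(w - best) < 1e-9:
            trees.append(combo)
    out = set()
    for combo in trees:
        out |= {frozenset((u, v)) for u, v, _ in combo}
    return out


class TestBuildMsn:
    def test_unique_mst_no_loop(self):
        steps = dm("ABC", {("A", "B"): 1, ("B", "C"): 1, ("A", "C"): 2})
        net = build_msn(steps)
        assert set(map(frozenset, net.edges)) == {
            frozenset("AB"), frozenset("BC")
        }

    def test_equilateral_keeps_loop(self):
        steps = dm("ABC", {("A", "B"): 1, ("B", "C"): 1, ("A", "C"): 1})
        net = build_msn(steps)
        assert net.number_of_edges() == 3

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_union_of_msts(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        labels = [f"h{i}" for i in range(n)]
        v = rng.integers(1, 6, size=(n, n))
        v = np.triu(v, 1)
        steps = DistanceMatrix(tuple(labels), v + v.T, "mutation-steps")
        net = build_msn(steps)
        got = {frozenset((u, v_)) for u, v_ in net.edges}
        assert got == oracle_msn_edges(steps)

    def test_contains_an_mst_of_minimum_weight(self):
        rng = np.random.default_rng(42)
        n = 7
        labels = [f"h{i}" for i in range(n)]
        v = rng.integers(1, 6, size=(n, n))
        v = np.triu(v, 1)
        steps = DistanceMatrix(tuple(labels), v + v.T, "mutation-steps")
        net = build_msn(steps)
        for u, v_ in net.edges:
            i, j = labels.index(u), labels.index(v_)
            net.edges[u, v_]["weight"] = steps.values[i, j]
        full = nx.Graph()
        for i in range(n):
            for j in range(i + 1, n):
                full.add_edge(labels[i], labels[j], weight=steps.values[i, j])
        t_net = nx.minimum_spanning_tree(net)
        t_full = nx.minimum_spanning_tree(full)
        assert t_net.size(weight="weight") == t_full.size(weight="weight")


def table_for(counts_and_coords):
    rows = tuple(
        PopulationRow(f"p{i}", "w", lat, lon, counts)
        for i, (counts, lat, lon) in enumerate(counts_and_coords)
    )
    return SampleTable(rows)


class TestResolveLoops:
    def test_frequency_rule(self):
        steps = dm("ABC", {("A", "B"): 1, ("B", "C"): 1, ("A", "C"): 1})
        net = build_msn(steps)
        table = table_for([({"A": 10, "B": 10, "C": 1}, 43.0, 141.0)])
        out = resolve_loops(net, table)
        assert nx.is_tree(out)
        assert out.has_edge("A", "B")  # high-count edge retained

    def test_geography_rule(self):
        steps = dm("ABC", {("A", "B"): 1, ("B", "C"): 1, ("A", "C"): 1})
        net = build_msn(steps)
        # equal counts; C sampled ~500 km away, farther from A than from B
        table = table_for(
            [
                ({"A": 5}, 43.0, 141.0),
                ({"B": 5}, 43.5, 141.0),
                ({"C": 5}, 47.8, 141.0),
            ]
        )
        out = resolve_loops(net, table)
        assert nx.is_tree(out)
        assert not out.has_edge("A", "C")  # C's far edge deleted

    def test_acyclic_input_identity(self):
        steps = dm("ABC", {("A", "B"): 1, ("B", "C"): 2, ("A", "C"): 4})
        net = build_msn(steps)
        out = resolve_loops(net, None)
        assert set(out.edges) == set(net.edges)

    def test_never_disconnects(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 6
            labels = [f"h{i}" for i in range(n)]
            v = rng.integers(1, 4, size=(n, n))
            v = np.triu(v, 1)
            steps = DistanceMatrix(tuple(labels), v + v.T, "mutation-steps")
            out = resolve_loops(build_msn(steps), None)
            assert nx.is_connected(out)
            assert out.number_of_edges() == n - 1


class TestInsertMissing:
    def test_single_weight3_edge(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=3)
        out = insert_missing(g)
        latent = [n for n in out if not out.nodes[n].get("observed", True)]
        assert len(latent) == 2
        assert out.number_of_edges() == 3
        assert nx.shortest_path_length(out, "A", "B") == 3

    def test_unit_network_identity(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1)
        g.add_edge("B", "C", weight=1)
        out = insert_missing(g)
        assert set(out.nodes) == {"A", "B", "C"}

    def test_preserves_all_pairwise_distances(self):
        rng = np.random.default_rng(11)
        g = nx.random_labeled_tree(8, seed=5)
        g = nx.relabel_nodes(g, {i: f"h{i}" for i in range(8)})
        for u, v in g.edges:
            g.edges[u, v]["weight"] = int(rng.integers(1, 5))
        out = insert_missing(g)
        for a in g.nodes:
            for b in g.nodes:
                want = nx.shortest_path_length(g, a, b, weight="weight")
                assert nx.shortest_path_length(out, a, b) == want

    def test_suppress_latent_inverts(self):
        g = nx.Graph()
        g.add_node("A", observed=True)
        g.add_node("B", observed=True)
        g.add_edge("A", "B", weight=4)
        back = suppress_latent(insert_missing(g))
        assert set(back.nodes) == {"A", "B"}
        assert back.edges["A", "B"]["weight"] == 4


class TestSplitLineages:
    def test_single_deep_bridge(self):
        g = nx.Graph()
        for a, b in [("A", "B"), ("B", "C")]:
            g.add_edge(a, b, weight=1)
        g.add_edge("C", "D", weight=7)
        g.add_edge("D", "E", weight=1)
        lm = split_lineages(g, 5)
        assert lm.lineages == ["L1", "L2"]
        assert set(lm.members("L1")) == {"A", "B", "C"}  # largest first
        assert set(lm.members("L2")) == {"D", "E"}

    def test_all_unit_edges_single_lineage(self):
        g = nx.path_graph(["A", "B", "C"])
        nx.set_edge_attributes(g, 1, "weight")
        assert split_lineages(g, 5).lineages == ["L1"]

    def test_two_bridges_three_lineages(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=6)
        g.add_edge("B", "C", weight=8)
        assert len(split_lineages(g, 5).lineages) == 3


class TestInferAncestor:
    def test_star_center_with_high_count(self):
        g = nx.star_graph(["K", "a", "b", "c", "d"])
        counts = {"K": 30, "a": 1, "b": 1, "c": 1, "d": 1}
        assert infer_ancestor(g, g.nodes, counts) == "K"

    def test_path_middle_by_eccentricity(self):
        g = nx.path_graph(["A", "B", "C", "D", "E"])
        counts = {n: 5 for n in g}
        assert infer_ancestor(g, g.nodes, counts) == "C"

    def test_latent_ineligible(self):
        g = nx.path_graph(["A", "m1", "B"])
        g.nodes["m1"]["observed"] = False
        counts = {"A": 5, "B": 5}
        # m1 has minimal eccentricity but cannot win
        assert infer_ancestor(g, g.nodes, counts) in {"A", "B"}


class TestNestClades:
    def test_path_of_five(self):
        g = nx.path_graph(["A", "B", "C", "D", "E"])
        nc = nest_clades(g)
        level1 = set(nc.levels[1])
        assert frozenset({"A", "B"}) in level1
        assert frozenset({"C", "D", "E"}) in level1  # stranded C absorbed

    def test_star_single_clade(self):
        g = nx.star_graph(["K", "a", "b", "c", "d"])
        nc = nest_clades(g)
        assert nc.levels[1] == (frozenset({"K", "a", "b", "c", "d"}),)

    @pytest.mark.parametrize("seed", range(5))
    def test_each_level_is_a_partition(self, seed):
        g = nx.random_labeled_tree(10, seed=seed)
        g = nx.relabel_nodes(g, {i: f"h{i}" for i in range(10)})
        nc = nest_clades(g)
        for level in nc.levels:
            seen = [n for clade in level for n in clade]
            assert sorted(seen) == sorted(g.nodes)

    def test_levels_are_coarsenings(self):
        g = nx.random_labeled_tree(12, seed=9)
        g = nx.relabel_nodes(g, {i: f"h{i}" for i in range(12)})
        nc = nest_clades(g)
        for lower, upper in zip(nc.levels, nc.levels[1:]):
            for clade in lower:
                containers = [c for c in upper if clade <= c]
                assert len(containers) == 1
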