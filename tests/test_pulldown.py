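"""Network extraction, pruning, capping and merging."""

import itertools

import networkx as nx
import numpy as np
import pytest

from pullnet.assoc_map import SeedMap
from pullnet.pulldown import (
    Interactome,
    NetworkModule,
    PulldownParams,
    annotate_metabolites,
    cap_network,
    filter_interactome,
    first_order_network,
    merge_overlapping,
    prune_overconnected,
    run_pulldown,
)


def graph_of(edges):
    return Interactome.from_edges(edges)


def module(nid, nodes, seeds=(), g=None):
    nodes = frozenset(nodes)
    edges = frozenset()
    if g is not None:
        edges = frozenset(
            frozenset(e) for e in g.graph.subgraph(nodes).edges
        )
    return NetworkModule(
        network_id=nid, nodes=nodes, edges=edges, seed_proteins=frozenset(seeds)
    )


class TestFilter:
    def test_drops_low_confidence_edges_and_isolated_nodes(self):
        g = graph_of([("A", "B", 0.05), ("B", "C", 0.5)])
        out = filter_interactome(g, 0.1)
        assert set(out.graph.nodes) == {"B", "C"}
        assert out.n_edges == 1

    def test_zero_threshold_is_identity(self):
        g = graph_of([("A", "B", 0.05), ("B", "C", 0.5)])
        out = filter_interactome(g, 0.0)
        assert out.n_edges == 2

    def test_matches_bruteforce_count(self, small_sim):
        g = small_sim["interactome"]
        out = filter_interactome(g, 0.1)
        expected = sum(
            1 for *_, c in g.graph.edges(data="confidence") if c >= 0.1
        )
        assert out.n_edges == expected

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            filter_interactome(graph_of([("A", "B", 0.5)]), 1.5)


class TestFirstOrder:
    def test_star(self):
        g = graph_of([("S", f"L{i}", 0.9) for i in range(4)])
        m = first_order_network(g, "S")
        assert m.size == 5 and len(m.edges) == 4
        assert m.seed_proteins == {"S"}

    def test_triangle_is_induced(self):
        g = graph_of([("A", "B", 0.9), ("B", "C", 0.9), ("A", "C", 0.9)])
        m = first_order_network(g, "A")
        assert m.size == 3 and len(m.edges) == 3  # includes the B-C edge

    def test_star_convention_drops_neighbor_edges(self):
        g = graph_of([("A", "B", 0.9), ("B", "C", 0.9), ("A", "C", 0.9)])
        m = first_order_network(g, "A", neighborhood="star")
        assert m.size == 3 and len(m.edges) == 2

    def test_missing_seed_warns_and_returns_empty(self):
        g = graph_of([("A", "B", 0.9)])
        with pytest.warns(UserWarning):
            m = first_order_network(g, "Z")
        assert m.size == 0

    def test_matches_bruteforce_neighborhood_induction(self, small_sim):
        g = filter_interactome(small_sim["interactome"], 0.1)
        seeds = small_sim["seed_map"].union_seed_list[:20]
        for s in seeds:
            if s not in g.graph:
                continue
            m = first_order_network(g, s)
            nodes = {s} | set(g.graph.neighbors(s))
            assert m.nodes == nodes
            expected_edges = {
                frozenset((u, v))
                for u, v in itertools.combinations(sorted(nodes), 2)
                if g.graph.has_edge(u, v)
            }
            assert m.edges == expected_edges


class TestPrune:
    def make_hub_instance(self):
        # module of 20 around seed S; hub H has 2 in-module edges and 500
        # external ones; the 99th-percentile degree in g is far below 500
        edges = [("S", f"M{i}", 0.9) for i in range(18)]
        edges += [("H", "S", 0.9), ("H", "M0", 0.9)]
        edges += [("H", f"X{i}", 0.9) for i in range(500)]
        g = graph_of(edges)
        m = first_order_network(g, "S")
        assert "H" in m.nodes
        return g, m

    def test_hub_removed(self):
        g, m = self.make_hub_instance()
        out = prune_overconnected(m, g, degree_percentile=0.99, inside_fraction_min=0.10)
        assert "H" not in out.nodes
        assert "S" in out.nodes

    def test_seed_never_removed(self, small_sim):
        g = filter_interactome(small_sim["interactome"], 0.1)
        for s in small_sim["seed_map"].union_seed_list[:10]:
            if s not in g.graph:
                continue
            m = first_order_network(g, s)
            out = prune_overconnected(m, g, degree_percentile=0.0, inside_fraction_min=1.0)
            assert s in out.nodes

    def test_no_qualifying_node_is_identity(self):
        g = graph_of([("A", "B", 0.9), ("B", "C", 0.9)])
        m = first_order_network(g, "B")
        assert prune_overconnected(m, g) == m

    def test_monotone_in_inside_fraction(self, small_sim):
        g = filter_interactome(small_sim["interactome"], 0.1)
        s = small_sim["seed_map"].union_seed_list[0]
        m = first_order_network(g, s)
        sizes = [
            prune_overconnected(m, g, 0.90, f).size
            for f in (0.0, 0.05, 0.10, 0.5, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestCap:
    def build_large_module(self, n=300):
        edges = [("S", f"N{i:03d}", 0.1 + 0.8 * (i / n)) for i in range(n)]
        g = graph_of(edges)
        return g, first_order_network(g, "S")

    def test_cap_retains_exactly_max_nodes_including_seed(self):
        g, m = self.build_large_module()
        out = cap_network(m, g, max_nodes=200)
        assert out.size == 200
        assert "S" in out.nodes

    def test_small_module_unchanged(self):
        g, m = self.build_large_module(n=150)
        assert cap_network(m, g, max_nodes=200) == m

    def test_exemption_skips_cap(self):
        g, m = self.build_large_module()
        out = cap_network(m, g, max_nodes=200, exemption_q=1e-4, seed_enrichment_q=1e-5)
        assert out.size == 301 and out.cap_exempt

    def test_ranking_matches_bruteforce_with_tiebreak(self):
        # equal confidences force the ascending-id tie-break
        edges = [("S", f"N{i:02d}", 0.5) for i in range(30)]
        g = graph_of(edges)
        m = first_order_network(g, "S")
        out = cap_network(m, g, max_nodes=11)
        assert out.nodes == {"S"} | {f"N{i:02d}" for i in range(10)}

    def test_survivors_are_highest_confidence_neighbors(self):
        g, m = self.build_large_module(n=50)
        out = cap_network(m, g, max_nodes=21)
        kept = sorted(out.nodes - {"S"})
        expected = sorted(f"N{i:03d}" for i in range(30, 50))  # top 20 by confidence
        assert kept == expected


class TestMerge:
    def complete_graph(self, names):
        return graph_of(
            [(a, b, 0.9) for a, b in itertools.combinations(sorted(names), 2)]
        )

    def test_containment_merges_engulfed_network(self):
        g = self.complete_graph("ABCD")
        n1 = module("n1", "ABCD", seeds="A", g=g)
        n2 = module("n2", "ABC", seeds="B", g=g)
        out = merge_overlapping([n1, n2], g)
        assert len(out) == 1
        assert out[0].nodes == frozenset("ABCD")
        assert out[0].seed_proteins == frozenset("AB")
        assert set(out[0].merged_from) == {"n1", "n2"}

    def test_half_overlap_kept_separate(self):
        g = self.complete_graph("ABCDEF")
        n1 = module("n1", "ABCD", g=g)
        n2 = module("n2", "ABEF", g=g)
        assert len(merge_overlapping([n1, n2], g)) == 2

    def test_whitelist_blocks_merge(self):
        g = self.complete_graph("ABCD")
        n1 = module("n1", "ABCD", g=g)
        n2 = module("n2", "ABC", g=g)
        out = merge_overlapping(
            [n1, n2], g, whitelist=frozenset({frozenset({"n1", "n2"})})
        )
        assert len(out) == 2

    @staticmethod
    def bruteforce_merge(mods, g, tau=0.75):
        """Exhaustive oracle: recompute all pairwise overlaps each round."""
        mods = {m.network_id: m for m in mods}
        while True:
            best = None
            for a, b in itertools.combinations(sorted(mods), 2):
                na, nb = mods[a].nodes, mods[b].nodes
                ov = len(na & nb) / min(len(na), len(nb))
                if ov > tau and (best is None or ov > best[0]):
                    best = (ov, a, b)
            if best is None:
                return {frozenset(m.nodes) for m in mods.values()}
            _, a, b = best
            ma, mb = mods.pop(a), mods.pop(b)
            nodes = ma.nodes | mb.nodes
            mods[min(a, b)] = NetworkModule(
                network_id=min(a, b), nodes=nodes,
                edges=frozenset(
                    frozenset(e) for e in g.graph.subgraph(nodes).edges
                ),
                seed_proteins=ma.seed_proteins | mb.seed_proteins,
            )

    def test_fixpoint_and_oracle_on_random_modules(self):
        r = np.random.default_rng(3)
        universe = [f"P{i:02d}" for i in range(40)]
        g = self.complete_graph(universe)
        mods = []
        for i in range(30):
            size = int(r.integers(3, 12))
            nodes = r.choice(universe, size=size, replace=False)
            mods.append(module(f"m{i:02d}", nodes, g=g))
        out = merge_overlapping(mods, g, overlap_min=0.75)
        # fixpoint: no remaining pair exceeds the threshold
        for m1, m2 in itertools.combinations(out, 2):
            ov = len(m1.nodes & m2.nodes) / min(len(m1.nodes), len(m2.nodes))
            assert ov <= 0.75
        assert {frozenset(m.nodes) for m in out} == self.bruteforce_merge(mods, g)


class TestAnnotate:
    def test_intersecting_seed_sets_link_metabolite(self):
        g = graph_of([("P1", "P2", 0.9)])
        m = first_order_network(g, "P1")
        sm = SeedMap({"histidine": frozenset({"P1"}), "caprate": frozenset({"Z9"})})
        out = annotate_metabolites(m, sm)
        assert out.linked_metabolites == {"histidine"}

    def test_counts_match_bruteforce_tally(self, small_sim):
        g = filter_interactome(small_sim["interactome"], 0.1)
        sm = small_sim["seed_map"]
        for s in sm.union_seed_list[:10]:
            if s not in g.graph:
                continue
            m = annotate_metabolites(first_order_network(g, s), sm)
            expected = {
                met for met, ps in sm.metabolite_to_proteins.items() if ps & m.nodes
            }
            assert m.linked_metabolites == expected


class TestRunPulldown:
    def toy_two_clique(self):
        cliqueA = [f"A{i}" for i in range(8)]
        cliqueB = [f"B{i}" for i in range(8)]
        edges = [(a, b, 0.9) for a, b in itertools.combinations(cliqueA, 2)]
        edges += [(a, b, 0.9) for a, b in itertools.combinations(cliqueB, 2)]
        # sparse background bridging
        edges += [("A0", "X0", 0.9), ("B0", "X1", 0.9), (f"X0", "X1", 0.9)]
        # plus extra filler so the graph has 30 nodes
        edges += [(f"Y{i}", f"Y{i+1}", 0.9) for i in range(12)]
        return Interactome.from_edges(edges)

    def test_two_planted_cliques_recovered(self):
        g = self.toy_two_clique()
        sm = SeedMap({"metA": frozenset({"A3"}), "metB": frozenset({"B5"})})
        mods, log = run_pulldown(g, sm)
        assert log["n_networks"] == 2
        node_sets = {frozenset(m.nodes) for m in mods}
        assert frozenset(f"A{i}" for i in range(8)) in node_sets
        assert frozenset(f"B{i}" for i in range(8)) in node_sets

    def test_zero_seeds_warns_empty(self):
        g = self.toy_two_clique()
        with pytest.warns(UserWarning):
            mods, log = run_pulldown(g, SeedMap({}))
        assert mods == [] and log["n_networks"] == 0

    def test_deterministic(self, small_sim):
        g, sm = small_sim["interactome"], small_sim["seed_map"]
        a, _ = run_pulldown(g, sm)
        b, _ = run_pulldown(g, sm)
        assert a == b

    def test_no_stage_removes_a_seed_from_its_module(self, small_sim):
        mods, _ = run_pulldown(small_sim["interactome"], small_sim["seed_map"])
        for m in mods:
            assert m.seed_proteins <= m.nodes
            assert m.seed_proteins
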