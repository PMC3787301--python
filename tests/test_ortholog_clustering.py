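import itertools

import networkx as nx
import numpy as np
import pytest

from melacog.ortholog_clustering import (
    best_hit_map,
    build_rbh_graph,
    form_clusters,
    quad_valid,
    reciprocal_best_hits,
)

GENOMES = ["A", "B", "C", "D"]


def make_graph(node_genomes, edges, score=100.0):
    g = nx.Graph()
    for node, genome in node_genomes.items():
        g.add_node(node, genome=genome)
    for edge in edges:
        if len(edge) == 3:
            a, b, s = edge
        else:
            a, b = edge
            s = score
        g.add_edge(a, b, score=s)
    return g


def quad_graph(edge_subset):
    """4 nodes a,b,c,d (one per genome) with the given subset of the 6 edges."""
    nodes = dict(zip("abcd", GENOMES))
    return make_graph(nodes, edge_subset)


ALL_PAIRS = list(itertools.combinations("abcd", 2))


class TestBestHitMap:
    def test_single_hit_per_query(self, make_hit):
        hits = [make_hit("q1", "s1"), make_hit("q2", "s2")]
        assert best_hit_map(hits) == {"q1": "s1", "q2": "s2"}

    def test_bitscore_tie_broken_by_evalue(self, make_hit):
        hits = [
            make_hit("q", "worse", bitscore=200.0, evalue=1e-10),
            make_hit("q", "better", bitscore=200.0, evalue=1e-20),
        ]
        assert best_hit_map(hits) == {"q": "better"}

    def test_full_tie_broken_lexicographically(self, make_hit):
        hits = [make_hit("q", "sB"), make_hit("q", "sA")]
        assert best_hit_map(hits) == {"q": "sA"}

    def test_no_hits_empty_map(self):
        assert best_hit_map([]) == {}


class TestReciprocalBestHits:
    def test_mutual_pair_is_edge(self):
        assert reciprocal_best_hits({"a": "b"}, {"b": "a"}) == [("a", "b")]

    def test_one_directional_is_not(self):
        assert reciprocal_best_hits({"a": "b"}, {"b": "a2"}) == []

    def test_matches_pair_enumeration_on_random_maps(self, rng):
        for _ in range(50):
            na, nb = int(rng.integers(1, 8)), int(rng.integers(1, 8))
            m_ab = {f"a{i}": f"b{int(rng.integers(0, nb))}" for i in range(na)}
            m_ba = {f"b{j}": f"a{int(rng.integers(0, na))}" for j in range(nb)}
            expected = {
                (a, b)
                for a in m_ab
                for b in m_ba
                if m_ab[a] == b and m_ba[b] == a
            }
            assert set(reciprocal_best_hits(m_ab, m_ba)) == expected


class TestQuadValid:
    def test_complete_quad_is_valid(self):
        assert quad_valid(list("abcd"), quad_graph(ALL_PAIRS))

    def test_five_edges_is_valid(self):
        g = quad_graph([e for e in ALL_PAIRS if e != ("a", "b")])
        assert quad_valid(list("abcd"), g)

    def test_four_cycle_is_invalid(self):
        # degrees all 2: nobody is connected to all three others
        g = quad_graph([("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")])
        assert not quad_valid(list("abcd"), g)

    def test_exhaustive_against_degree_oracle(self):
        """All 64 labelled edge subsets of the 4-node graph."""
        for bits in range(64):
            edges = [e for k, e in enumerate(ALL_PAIRS) if bits >> k & 1]
            degree = {n: 0 for n in "abcd"}
            for a, b in edges:
                degree[a] += 1
                degree[b] += 1
            oracle = (
                sum(1 for d in degree.values() if d == 3) >= 2
                and min(degree.values()) >= 2
            )
            assert quad_valid(list("abcd"), quad_graph(edges)) == oracle, edges

    def test_member_count_and_genome_errors(self):
        g = quad_graph(ALL_PAIRS)
        with pytest.raises(ValueError):
            quad_valid(list("abc"), g)
        g2 = make_graph({"a": "A", "b": "A", "c": "C", "d": "D"}, [])
        with pytest.raises(ValueError):
            quad_valid(list("abcd"), g2)


class TestBuildRbhGraph:
    @staticmethod
    def _tables(make_hit, families):
        """Perfect 1:1 orthologs: family f has protein f_g in every genome."""
        genomes = {g: [f"{f}_{g}" for f in families] for g in GENOMES}
        tables = {}
        for ga, gb in itertools.permutations(GENOMES, 2):
            tables[(ga, gb)] = [
                make_hit(f"{f}_{ga}", f"{f}_{gb}", bitscore=500.0) for f in families
            ]
        return genomes, tables

    def test_perfect_orthologs_give_disjoint_k4(self, make_hit):
        genomes, tables = self._tables(make_hit, ["f1", "f2"])
        graph = build_rbh_graph(genomes, tables)
        comps = list(nx.connected_components(graph))
        assert sorted(len(c) for c in comps) == [4, 4]
        for comp in comps:
            assert graph.subgraph(comp).number_of_edges() == 6

    def test_missing_member_gives_k3(self, make_hit):
        genomes, tables = self._tables(make_hit, ["f1"])
        genomes["D"] = []
        for pair in list(tables):
            if "D" in pair:
                tables[pair] = []
        graph = build_rbh_graph(genomes, tables)
        (comp,) = [c for c in nx.connected_components(graph) if len(c) > 1]
        assert len(comp) == 3
        assert graph.subgraph(comp).number_of_edges() == 3

    def test_missing_pair_table_is_an_error(self, make_hit):
        genomes, tables = self._tables(make_hit, ["f1"])
        del tables[("A", "B")]
        with pytest.raises(ValueError, match="A vs B"):
            build_rbh_graph(genomes, tables)

    def test_degree_bounded_by_genome_count_on_fuzzed_inputs(self, rng, make_hit):
        for _ in range(20):
            genomes = {g: [f"{g}{i}" for i in range(int(rng.integers(1, 6)))] for g in GENOMES}
            tables = {}
            for ga, gb in itertools.permutations(GENOMES, 2):
                hits = []
                for q in genomes[ga]:
                    for s in genomes[gb]:
                        if rng.random() < 0.5:
                            hits.append(
                                make_hit(q, s, bitscore=float(rng.integers(50, 500)))
                            )
                tables[(ga, gb)] = hits
            graph = build_rbh_graph(genomes, tables)
            assert all(d <= len(GENOMES) - 1 for _, d in graph.degree)


class TestFormClusters:
    def test_disjoint_k4_components_each_form_a_cluster(self, make_hit):
        genomes, tables = TestBuildRbhGraph._tables(make_hit, ["f1", "f2", "f3"])
        graph = build_rbh_graph(genomes, tables)
        clusters = form_clusters(graph)
        assert len(clusters) == 3
        recovered = {frozenset(c.members.values()) for c in clusters}
        expected = {frozenset(f"f{i}_{g}" for g in GENOMES) for i in (1, 2, 3)}
        assert recovered == expected

    def test_overlapping_candidates_resolved_by_score(self):
        """Two valid quads share three members; the higher-scoring one wins."""
        nodes = {"a1": "A", "b1": "B", "c1": "C", "d1": "D", "d2": "D"}
        edges = [
            ("a1", "b1", 100.0),
            ("a1", "c1", 100.0),
            ("b1", "c1", 100.0),
            ("a1", "d1", 90.0),
            ("c1", "d1", 90.0),
            ("b1", "d2", 50.0),
            ("c1", "d2", 50.0),
        ]
        graph = make_graph(nodes, edges)
        assert quad_valid(["a1", "b1", "c1", "d1"], graph)
        assert quad_valid(["a1", "b1", "c1", "d2"], graph)
        clusters = form_clusters(graph)
        assert len(clusters) == 1
        assert clusters[0].members["D"] == "d1"

    def test_component_without_valid_quad_yields_nothing(self):
        nodes = {"a": "A", "b": "B", "c": "C", "d": "D"}
        graph = make_graph(nodes, [("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")])
        assert form_clusters(graph) == []

    def test_fuzzed_clusters_are_disjoint_and_valid(self, rng):
        for _ in range(30):
            nodes = {}
            for g in GENOMES:
                for i in range(int(rng.integers(1, 5))):
                    nodes[f"{g}{i}"] = g
            graph = make_graph(nodes, [])
            names = sorted(nodes)
            for a, b in itertools.combinations(names, 2):
                if nodes[a] != nodes[b] and rng.random() < 0.35:
                    graph.add_edge(a, b, score=float(rng.integers(10, 500)))
            clusters = form_clusters(graph)
            seen = set()
            for cl in clusters:
                members = list(cl.members.values())
                assert quad_valid(members, graph)
                assert not seen & set(members)
                seen.update(members)
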