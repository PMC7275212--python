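"""PPI graph construction, degree/harmonic-closeness, hub screening."""

import random
from fractions import Fraction
from math import lcm

import networkx as nx
import pytest

from netpharm import (CentralityRecord, GeneSet, ScoredEdge, ValidationError,
                      average_degree, build_graph, centrality_table,
                      filter_edges_by_confidence, harmonic_closeness,
                      harmonic_closeness_exact, node_degree, screen_hubs)
from oracles import degree_oracle, harmonic_closeness_oracle


def genes(n):
    return GeneSet("g", frozenset(f"N{i}" for i in range(n)))


def er_graph(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    nodes = [f"N{i}" for i in range(n)]
    edges = [ScoredEdge(nodes[a], nodes[b]) for a, b in g.edges()]
    return build_graph(edges, genes(n)), [(f"N{a}", f"N{b}") for a, b in g.edges()]


def test_confidence_filter_boundary():
    edges = [ScoredEdge("A", "B", 0.40), ScoredEdge("A", "C", 0.399),
             ScoredEdge("B", "C", None)]
    kept = filter_edges_by_confidence(edges)
    assert [(e.a, e.b) for e in kept] == [("A", "B"), ("B", "C")]


def test_confidence_filter_planted_count():
    rng = random.Random(3)
    scores = [rng.random() for _ in range(500)]
    edges = [ScoredEdge(f"A{i}", f"B{i}", s) for i, s in enumerate(scores)]
    expected = sum(1 for s in scores if s >= 0.4)
    assert len(filter_edges_by_confidence(edges)) == expected


def test_score_out_of_range_rejected():
    with pytest.raises(ValidationError):
        ScoredEdge("A", "B", 1.2)


def test_build_graph_collapses_duplicates_and_self_loops():
    g = build_graph([ScoredEdge("A", "B"), ScoredEdge("B", "A"), ScoredEdge("A", "A")],
                    GeneSet("g", frozenset({"A", "B", "C"})))
    assert g.number_of_nodes() == 3 and g.number_of_edges() == 1
    assert g.degree["C"] == 0
    assert g.graph["dropped_self_loops"] == 1


def test_build_graph_endpoint_outside_node_set():
    with pytest.raises(ValidationError, match="X"):
        build_graph([ScoredEdge("A", "X")], GeneSet("g", frozenset({"A", "B"})))


def test_degree_star_and_isolated():
    star = build_graph(
        [ScoredEdge("C", f"L{i}") for i in range(5)],
        GeneSet("g", frozenset({"C", "L0", "L1", "L2", "L3", "L4", "ISO"})))
    assert node_degree(star, "C") == 5
    assert node_degree(star, "ISO") == 0
    with pytest.raises(KeyError):
        node_degree(star, "nope")


def test_degree_matches_adjacency_oracle():
    g, edges = er_graph(30, 0.3, seed=3)
    nodes = [f"N{i}" for i in range(30)]
    for v in nodes:
        assert node_degree(g, v) == degree_oracle(nodes, edges, v)


def test_harmonic_closeness_path_closed_form():
    g = build_graph([ScoredEdge("A", "B"), ScoredEdge("B", "C")],
                    GeneSet("g", frozenset({"A", "B", "C"})))
    assert harmonic_closeness_exact(g, "A") == Fraction(3, 2)
    assert harmonic_closeness_exact(g, "B") == 2


@pytest.mark.parametrize("n", [3, 6, 10])
def test_harmonic_closeness_star_closed_form(n):
    nodes = GeneSet("g", frozenset({"C", *(f"L{i}" for i in range(n))}))
    g = build_graph([ScoredEdge("C", f"L{i}") for i in range(n)], nodes)
    assert harmonic_closeness_exact(g, "C") == n
    assert harmonic_closeness_exact(g, "L0") == 1 + Fraction(n - 1, 2)


def test_harmonic_closeness_matches_bfs_oracle():
    g, edges = er_graph(40, 0.15, seed=5)
    nodes = [f"N{i}" for i in range(40)]
    for v in nodes:
        assert harmonic_closeness_exact(g, v) == harmonic_closeness_oracle(
            nodes, edges, v)


def test_closeness_bounds_and_denominator():
    """0 <= closeness <= n-1, closeness >= degree, and the exact value's
    denominator divides lcm(1..diameter) on an unweighted graph."""
    g, edges = er_graph(25, 0.12, seed=9)
    nodes = [f"N{i}" for i in range(25)]
    diam = max(
        d for comp in nx.connected_components(g)
        for v in comp
        for d in nx.single_source_shortest_path_length(g, v).values()
    )
    bound = lcm(*range(1, max(diam, 1) + 1))
    for v in nodes:
        c = harmonic_closeness_exact(g, v)
        assert 0 <= c <= len(nodes) - 1
        assert c >= node_degree(g, v)
        assert bound % c.denominator == 0


def test_unreachable_nodes_contribute_zero():
    g = build_graph([ScoredEdge("A", "B")], GeneSet("g", frozenset({"A", "B", "C"})))
    assert harmonic_closeness(g, "A") == 1.0
    assert harmonic_closeness(g, "C") == 0.0


def test_average_degree_83_nodes_729_edges():
    g = nx.gnm_random_graph(83, 729, seed=1)
    nodes = GeneSet("g", frozenset(f"N{i}" for i in range(83)))
    graph = build_graph([ScoredEdge(f"N{a}", f"N{b}") for a, b in g.edges()], nodes)
    assert round(average_degree(graph), 1) == 17.6


def test_average_degree_edge_cases():
    g = build_graph([], genes(4))
    assert average_degree(g) == 0.0
    with pytest.raises(ValidationError):
        average_degree(build_graph([], GeneSet("g", frozenset())))


def test_average_degree_equals_mean_of_degrees():
    g, _ = er_graph(35, 0.2, seed=11)
    degs = [g.degree[v] for v in g.nodes]
    assert average_degree(g) == pytest.approx(sum(degs) / len(degs))


def naive_hub_filter(records, deg_min, clo_min):
    kept = [r for r in records if r.degree >= deg_min and r.closeness >= clo_min]
    return sorted(kept, key=lambda r: (-r.degree, -r.closeness, r.symbol))


def test_screen_hubs_reference_table(reference_centralities):
    """All 26 published centrality records pass the default joint screen,
    with the boundary record sitting exactly at degree 20 / closeness 48.33333."""
    hubs = screen_hubs(reference_centralities)
    assert len(hubs) == 26
    assert hubs[0].symbol == "IL-6" and hubs[0].degree == 50
    assert hubs[-1].symbol == "NQO1"
    assert min(h.degree for h in hubs) == 20
    assert min(h.closeness for h in hubs) == pytest.approx(48.33333)


def test_screen_hubs_excludes_below_either_threshold():
    recs = [CentralityRecord("A", 19, 60.0), CentralityRecord("B", 25, 40.0)]
    assert screen_hubs(recs) == []


def test_screen_hubs_matches_naive_oracle():
    rng = random.Random(17)
    recs = [CentralityRecord(f"G{i}", rng.randint(0, 40), rng.uniform(0, 70))
            for i in range(200)]
    got = screen_hubs(recs, 15, 30.0)
    want = naive_hub_filter(recs, 15, 30.0)
    assert [(r.symbol, r.degree, r.closeness) for r in got] == [
        (r.symbol, r.degree, r.closeness) for r in want]
    assert all(r.is_hub for r in got)


def test_screen_hubs_monotone(reference_centralities):
    base = len(screen_hubs(reference_centralities))
    assert len(screen_hubs(reference_centralities, deg_min=25)) <= base
    assert len(screen_hubs(reference_centralities, clo_min=55.0)) <= base


def test_centrality_table_sorted_and_consistent():
    g, edges = er_graph(20, 0.25, seed=2)
    table = centrality_table(g)
    assert [r.symbol for r in table] == [
        r.symbol for r in sorted(table, key=lambda r: (-r.degree, -r.closeness,
                                                       r.symbol))]
    by_symbol = {r.symbol: r for r in table}
    for v in g.nodes:
        assert by_symbol[v].degree == g.degree[v]
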