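"""PPI graph construction, centralities, and hub screening.

Closeness is implemented as harmonic centrality, the sum of reciprocal
shortest-path distances Σ_{u≠v} 1/d(v, u) with unreachable nodes
contributing zero.  On an unweighted graph this is an exact rational; it
is computed with Fraction arithmetic internally and rounded to five
decimals only at output, which is why published hub tables show
repeating decimals like 64.33333 (denominators dividing small lcms).
The textbook "inverse of the summed distance" definition (1/Σd) yields
values ≤ 1 on any connected graph of this size and cannot produce such
magnitudes; the harmonic form is the one network-analysis hub-screening
tools actually compute.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import networkx as nx

from .formulary import ValidationError
from .targets import GeneSet, normalize_symbol

DEFAULT_EDGE_SCORE_MIN = 0.4
DEFAULT_DEGREE_MIN = 20
DEFAULT_CLOSENESS_MIN = 48.33


@dataclass(frozen=True)
class ScoredEdge:
    """An undirected protein–protein association with optional confidence."""

    a: str
    b: str
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValidationError(
                f"edge ({self.a}, {self.b}): confidence {self.score!r} outside [0, 1]"
            )


@dataclass(frozen=True)
class CentralityRecord:
    symbol: str
    degree: int
    closeness: float
    is_hub: bool = False


def filter_edges_by_confidence(
    edges: Sequence[ScoredEdge], min_score: float = DEFAULT_EDGE_SCORE_MIN
) -> list[ScoredEdge]:
    """Keep scored edges with score >= min_score; unscored edges are trusted."""
    return [e for e in edges if e.score is None or e.score >= min_score]


def build_graph(edges: Sequence[ScoredEdge], nodes: GeneSet) -> nx.Graph:
    """Simple undirected graph over a fixed node set.

    Duplicate and reversed pairs collapse; self-loops are dropped (their
    count is stored on the graph as ``dropped_self_loops``).  Isolated
    nodes are legal.  Edge endpoints must lie inside the node set.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes.symbols)
    dropped = 0
    for e in edges:
        a, b = normalize_symbol(e.a), normalize_symbol(e.b)
        if a == b:
            dropped += 1
            continue
        for end in (a, b):
            if end not in nodes:
                raise ValidationError(f"edge endpoint {end!r} outside the node set")
        g.add_edge(a, b)
    g.graph["dropped_self_loops"] = dropped
    return g


def node_degree(g: nx.Graph, v: str) -> int:
    if v not in g:
        raise KeyError(f"unknown node {v!r}")
    return g.degree[v]


def harmonic_closeness_exact(g: nx.Graph, v: str) -> Fraction:
    """Exact harmonic centrality Σ_{u≠v} 1/d(v, u) over BFS distances."""
    if v not in g:
        raise KeyError(f"unknown node {v!r}")
    dist = nx.single_source_shortest_path_length(g, v)
    return sum((Fraction(1, d) for u, d in dist.items() if u != v), Fraction(0))


def harmonic_closeness(g: nx.Graph, v: str) -> float:
    """Harmonic centrality as a float (exact value rounded only by IEEE)."""
    return float(harmonic_closeness_exact(g, v))


def average_degree(g: nx.Graph) -> float:
    """Mean node degree, 2·|E| / |V| (exact; round at presentation time)."""
    if g.number_of_nodes() == 0:
        raise ValidationError("average degree undefined on an empty graph")
    return 2.0 * g.number_of_edges() / g.number_of_nodes()


def centrality_table(g: nx.Graph) -> list[CentralityRecord]:
    """Per-node degree and harmonic closeness, hub flag unset."""
    recs = [
        CentralityRecord(v, g.degree[v], float(harmonic_closeness_exact(g, v)))
        for v in g.nodes
    ]
    recs.sort(key=lambda r: (-r.degree, -r.closeness, r.symbol))
    return recs


def screen_hubs(
    records: Sequence[CentralityRecord],
    deg_min: int = DEFAULT_DEGREE_MIN,
    clo_min: float = DEFAULT_CLOSENESS_MIN,
) -> list[CentralityRecord]:
    """Joint inclusive degree/closeness threshold screen.

    Returns hubs sorted by degree descending, then closeness descending,
    then symbol ascending, each flagged ``is_hub=True``.  Thresholds are
    inclusive: published hub tables include boundary records sitting
    exactly at the degree and closeness cut-offs, so a strict reading
    would contradict the screen's own output.
    """
    hubs = [
        CentralityRecord(r.symbol, r.degree, r.closeness, True)
        for r in records
        if r.degree >= deg_min and r.closeness >= clo_min
    ]
    hubs.sort(key=lambda r: (-r.degree, -r.closeness, r.symbol))
    return hubs


def load_reference_centralities() -> list[CentralityRecord]:
    """Packaged hub-gene centrality table (26 records: degree, closeness)."""
    from importlib import resources
    from .io import read_centrality_table

    with resources.as_file(
        resources.files("netpharm.data").joinpath("hub_centralities.tsv")
    ) as p:
        return read_centrality_table(p)


def connected_components_report(g: nx.Graph) -> list[list[str]]:
    """Connected components, largest first.

    A coarse structural report only — this is not a modularity or
    k-means style module decomposition.
    """
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c))
    return comps
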