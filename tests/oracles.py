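"""Independent brute-force oracles used to cross-check the library.

Everything here is deliberately naive and self-contained (no networkx,
no scipy) so that a disagreement with the package implicates the
package, not a shared dependency.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


def bfs_distances(adj: dict, source):
    """Plain-queue BFS over an adjacency dict; returns {node: distance}."""
    dist = {source: 0}
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def adjacency_from_edges(nodes, edges):
    adj = {v: set() for v in nodes}
    for a, b in edges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    return adj


def harmonic_closeness_oracle(nodes, edges, v) -> Fraction:
    """Σ_{u≠v} 1/d(v,u) with unreachable nodes contributing 0."""
    adj = adjacency_from_edges(nodes, edges)
    dist = bfs_distances(adj, v)
    return sum((Fraction(1, d) for u, d in dist.items() if u != v), Fraction(0))


def degree_oracle(nodes, edges, v) -> int:
    return len(adjacency_from_edges(nodes, edges)[v])


def hypergeom_tail_enum(k: int, K: int, n: int, N: int) -> Fraction:
    """P[X >= k] by enumerating every size-n draw from a population of N
    whose first K elements are the successes."""
    hits = sum(
        1
        for draw in combinations(range(N), n)
        if sum(1 for x in draw if x < K) >= k
    )
    return Fraction(hits, comb(N, n))


def hypergeom_tail_table(K: int, n: int, N: int) -> dict:
    """{k: P[X >= k]} for all feasible k, from one exhaustive enumeration."""
    total = comb(N, n)
    hist = {}
    for draw in combinations(range(N), n):
        x = sum(1 for e in draw if e < K)
        hist[x] = hist.get(x, 0) + 1
    table = {}
    running = 0
    for k in sorted(hist, reverse=True):
        running += hist[k]
        table[k] = Fraction(running, total)
    # tails for k below the smallest observed overlap are 1 by construction
    for k in range(min(hist), -1, -1):
        table[k] = Fraction(1)
    return table


def bh_naive(pvalues):
    """Step-up Benjamini–Hochberg: sort, scale by m/rank, cumulative min
    from the largest rank, clip at 1, restore input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q


def kappa_contingency(x, y) -> float:
    """Cohen's kappa from the 2x2 contingency table, written out by hand."""
    n = len(x)
    a = sum(1 for i in range(n) if x[i] and y[i])
    b = sum(1 for i in range(n) if x[i] and not y[i])
    c = sum(1 for i in range(n) if not x[i] and y[i])
    d = n - a - b - c
    po = (a + d) / n
    pe = ((a + b) / n) * ((a + c) / n) + ((c + d) / n) * ((b + d) / n)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)
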