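"""Hypergeometric over-representation analysis with kappa term clustering.

Given an input gene list (typically the hub genes of the interaction
network) and a flat term database (GMT), each term is scored by the
upper-tail hypergeometric probability of observing at least k of the n
input genes inside a term of K members drawn from a background of N
genes.  Benjamini–Hochberg adjustment is applied across all tested
terms, and terms surviving the significance / minimum-count /
enrichment-factor filter are grouped into clusters of redundant terms by
Cohen's kappa agreement of their membership vectors over the input list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence, Union

import networkx as nx
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .formulary import ValidationError
from .targets import GeneSet

log = logging.getLogger(__name__)

DEFAULT_P_MAX = 0.01
DEFAULT_MIN_COUNT = 3
DEFAULT_MIN_FACTOR = 1.5
DEFAULT_KAPPA_MIN = 0.3


@dataclass(frozen=True)
class TermDB:
    """A flat annotation database: (term id, category, description, members)."""

    terms: tuple[tuple[str, str, str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        ids = [t[0] for t in self.terms]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate term ids in TermDB")
        for tid, _, _, members in self.terms:
            if not members:
                raise ValidationError(f"term {tid!r} has an empty member set")

    def members(self, term_id: str) -> frozenset[str]:
        for tid, _, _, m in self.terms:
            if tid == term_id:
                return m
        raise KeyError(term_id)

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, _, _, m in self.terms:
            out |= m
        return frozenset(out)


@dataclass(frozen=True)
class EnrichmentTerm:
    """One scored term: counts, probabilities and derived columns."""

    term_id: str
    category: str
    description: str
    k: int  # input genes in term ("Count")
    K: int  # background genes in term
    n: int  # input-list size (after background restriction)
    N: int  # background size
    p: float
    q: float = math.nan
    cluster_id: Optional[int] = None

    @property
    def percent(self) -> float:
        return percent_of_input(self.k, self.n)

    @property
    def enrichment_factor(self) -> float:
        return (self.k / self.n) / (self.K / self.N)

    @property
    def log10_p(self) -> float:
        return math.log10(self.p)

    @property
    def log10_q(self) -> float:
        return math.log10(self.q)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    X counts successes in a size-n draw without replacement from a
    population of N containing K successes:
    Σ_{i=k}^{min(n,K)} C(K,i) C(N−K,n−i) / C(N,n).
    """
    if k < 0 or K < 0 or n < 0 or N < 0 or K > N or n > N or k > K or k > n:
        raise ValidationError(f"inconsistent counts (k={k}, K={K}, n={n}, N={N})")
    # sf(k-1) = P[X >= k]
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    if len(pvalues) == 0:
        return []
    for p in pvalues:
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"p-value {p!r} outside (0, 1]")
    return list(multipletests(list(pvalues), method="fdr_bh")[1])


def percent_of_input(k: int, n: int) -> float:
    """100·k/n, rounded half-up to two decimals (the "%" column)."""
    if n < 1:
        raise ValidationError("percent undefined for empty input list")
    if not (0 <= k <= n):
        raise ValidationError(f"count k={k} outside [0, {n}]")
    return float(
        (Decimal(100 * k) / Decimal(n)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


def enrich(
    genes: GeneSet,
    db: TermDB,
    background: Union[GeneSet, str] = "auto",
    p_max: float = DEFAULT_P_MAX,
    min_count: int = DEFAULT_MIN_COUNT,
    min_factor: float = DEFAULT_MIN_FACTOR,
) -> list[EnrichmentTerm]:
    """Over-representation scan of ``genes`` against ``db``.

    ``background="auto"`` uses the union of all term members as the
    universe.  Input genes absent from the background are dropped with a
    logged warning and the effective list size n reduced accordingly.
    Filters follow the conventional cut-offs: strict p < p_max,
    inclusive count >= min_count, strict enrichment factor > min_factor;
    q-values are computed across all tested terms before filtering.
    """
    universe = db.universe() if background == "auto" else background.symbols
    inside = genes.symbols & universe
    if not inside:
        raise ValidationError(
            f"gene list entirely outside the background: {sorted(genes.symbols)}"
        )
    dropped = genes.symbols - inside
    if dropped:
        log.warning("dropping %d input genes absent from background: %s",
                    len(dropped), sorted(dropped))
    n, N = len(inside), len(universe)

    tested: list[EnrichmentTerm] = []
    for tid, cat, desc, members in db.terms:
        members_bg = members & universe
        k = len(inside & members_bg)
        if k < 1:
            continue
        K = len(members_bg)
        tested.append(
            EnrichmentTerm(tid, cat, desc, k, K, n, N, hypergeom_tail(k, K, n, N))
        )
    if not tested:
        return []
    qs = bh_adjust([t.p for t in tested])
    tested = [replace(t, q=q) for t, q in zip(tested, qs)]
    kept = [
        t for t in tested
        if t.p < p_max and t.k >= min_count and t.enrichment_factor > min_factor
    ]
    kept.sort(key=lambda t: (t.p, t.term_id))
    return kept


def load_reference_clusters():
    """Packaged enriched-cluster table (term id, count, percent, log p/q)."""
    import pandas as pd
    from importlib import resources

    with resources.as_file(
        resources.files("netpharm.data").joinpath("enriched_clusters.tsv")
    ) as p:
        return pd.read_csv(p, sep="\t")


def cohen_kappa(x: Sequence[bool], y: Sequence[bool]) -> float:
    """Cohen's kappa between two equal-length binary vectors."""
    if len(x) != len(y) or not x:
        raise ValidationError("kappa requires two equal-length non-empty vectors")
    n = len(x)
    a = sum(1 for i, j in zip(x, y) if i and j)
    b = sum(1 for i, j in zip(x, y) if i and not j)
    c = sum(1 for i, j in zip(x, y) if not i and j)
    d = n - a - b - c
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def kappa_cluster(
    terms: Sequence[EnrichmentTerm],
    db: TermDB,
    genes: GeneSet,
    kappa_min: float = DEFAULT_KAPPA_MIN,
) -> list[EnrichmentTerm]:
    """Group redundant enriched terms by membership agreement.

    Terms are linked when Cohen's kappa of their binary membership
    vectors over the input gene list reaches ``kappa_min``; clusters are
    the connected components of the link graph.  Each cluster is labeled
    by its lowest-p member, and cluster ids are assigned in order of
    that representative's p (1 = most significant).  Returns the terms
    with ``cluster_id`` filled in, original order preserved.
    """
    if not terms:
        raise ValidationError("kappa_cluster requires at least one term")
    gene_order = sorted(genes.symbols)
    vec = {
        t.term_id: [g in db.members(t.term_id) for g in gene_order] for t in terms
    }
    g = nx.Graph()
    g.add_nodes_from(t.term_id for t in terms)
    for i, t1 in enumerate(terms):
        for t2 in terms[i + 1:]:
            if cohen_kappa(vec[t1.term_id], vec[t2.term_id]) >= kappa_min:
                g.add_edge(t1.term_id, t2.term_id)
    best_p = {t.term_id: (t.p, t.term_id) for t in terms}
    comps = sorted(nx.connected_components(g), key=lambda c: min(best_p[t] for t in c))
    assign = {tid: ci for ci, comp in enumerate(comps, start=1) for tid in comp}
    return [replace(t, cluster_id=assign[t.term_id]) for t in terms]
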