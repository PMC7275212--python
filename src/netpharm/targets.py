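"""Gene-symbol normalization, target-set assembly and Venn intersection.

Per-herb target sets (union over each herb's screened ingredients) are
intersected with a merged disease-target set; the union of the per-herb
intersections, deduplicated, is the "key target" set that seeds the
interaction network and every downstream stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .formulary import ValidationError

_WS = re.compile(r"\s+")

GENECARDS_LIKE = "genecards-like"
OMIM_LIKE = "omim-like"

DEFAULT_GIFTS_MIN = 30.0


def normalize_symbol(raw: str, alias: Optional[Mapping[str, str]] = None) -> str:
    """Canonicalize a gene symbol: trim, uppercase, collapse whitespace.

    An optional alias table (exact-match lookup, applied after
    normalization) lets callers inject externally derived symbol
    mappings, e.g. UniProt-official renames.
    """
    s = _WS.sub(" ", raw.strip()).upper()
    if not s:
        raise ValidationError(f"empty gene symbol after trimming: {raw!r}")
    if alias:
        s = alias.get(s, s)
    return s


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of canonical gene symbols."""

    label: str
    symbols: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for s in self.symbols:
            if not s or s != s.strip() or s != s.upper():
                raise ValidationError(f"{self.label}: non-canonical symbol {s!r}")

    @classmethod
    def from_raw(
        cls,
        label: str,
        raw_symbols: Iterable[str],
        alias: Optional[Mapping[str, str]] = None,
    ) -> "GeneSet":
        return cls(label, frozenset(normalize_symbol(s, alias) for s in raw_symbols))

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def __iter__(self):
        return iter(sorted(self.symbols))


@dataclass(frozen=True)
class DiseaseTargetRecord:
    """One disease-associated gene with an optional functionality score.

    Scored records emulate GeneCards-style exports carrying a GIFtS-like
    functionality score; unscored records emulate OMIM-style catalogue
    entries, which carry none and bypass the score filter.
    """

    symbol: str
    score: Optional[float] = None
    source: str = GENECARDS_LIKE

    def __post_init__(self) -> None:
        if self.score is not None and self.score < 0:
            raise ValidationError(f"{self.symbol}: negative functionality score")
        if self.source not in (GENECARDS_LIKE, OMIM_LIKE):
            raise ValidationError(f"{self.symbol}: unknown source {self.source!r}")


@dataclass(frozen=True)
class VennReport:
    """Per-herb intersections with the disease set, and their union."""

    per_herb_intersections: dict[str, GeneSet]
    per_herb_counts: dict[str, int]
    key_targets: GeneSet


def herb_target_union(edges: Sequence[tuple[str, str, str]], herb: str) -> GeneSet:
    """Union of target symbols across one herb's ingredients.

    ``edges`` are (mol_id, herb, target symbol) triples with symbols
    already normalized (see :class:`netpharm.network.CompoundTargetMap`).
    """
    herbs_present = {h for _, h, _ in edges}
    if herb not in herbs_present:
        raise KeyError(f"no compound-target edges for herb {herb!r}")
    return GeneSet(herb, frozenset(t for _, h, t in edges if h == herb))


def filter_disease_targets(
    records: Sequence[DiseaseTargetRecord],
    score_min: float = DEFAULT_GIFTS_MIN,
    label: str = "disease",
) -> GeneSet:
    """Keep scored records with score >= score_min; unscored kept always."""
    if score_min < 0:
        raise ValidationError(f"score_min must be non-negative, got {score_min!r}")
    kept = {
        normalize_symbol(r.symbol)
        for r in records
        if r.score is None or r.score >= score_min
    }
    return GeneSet(label, frozenset(kept))


def merge_disease_sources(a: GeneSet, b: GeneSet, label: str = "disease") -> GeneSet:
    """Redundancy-eliminating union of two disease-target sources."""
    return GeneSet(label, a.symbols | b.symbols)


def venn3(herb_sets: Mapping[str, GeneSet], disease: GeneSet) -> VennReport:
    """Intersect each herb's target set with the disease set.

    The key-target set is the deduplicated union of the per-herb
    intersections, reported alongside per-herb counts.
    """
    if not herb_sets:
        raise ValidationError("venn3 requires at least one herb target set")
    inter: dict[str, GeneSet] = {}
    counts: dict[str, int] = {}
    union: set[str] = set()
    for herb, gs in herb_sets.items():
        common = gs.symbols & disease.symbols
        inter[herb] = GeneSet(herb, frozenset(common))
        counts[herb] = len(common)
        union |= common
    return VennReport(inter, counts, GeneSet("key_targets", frozenset(union)))
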