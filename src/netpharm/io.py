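"""Readers and writers for the pipeline's tabular dialects.

All tables are UTF-8 TSV with a header row, locale-independent decimal
points and either LF or CRLF line endings.  Gene lists are one symbol
per line; term databases use the standard GMT layout (term id,
description, then member symbols).  Every writer emits a dialect its
paired reader round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .enrichment import EnrichmentTerm, TermDB
from .formulary import Formulary, Ingredient, ValidationError
from .metrics import CentralityRecord, ScoredEdge
from .network import CompoundTargetMap
from .targets import DiseaseTargetRecord, GeneSet, normalize_symbol, GENECARDS_LIKE


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise ValidationError(f"{path}: cannot parse as TSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: header missing column(s) {missing}")
    return df


def _num(path: Path, row: int, col: str, raw: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ValidationError(
            f"{path}: line {row + 2}, column {col!r}: non-numeric value {raw!r}"
        ) from None


def read_ingredient_table(path: str | Path) -> Formulary:
    path = Path(path)
    df = _read_tsv(path, ["mol_id", "name", "ob", "dl", "herb"])
    herbs: list[str] = []
    ingredients = []
    for i, row in df.iterrows():
        if row["herb"] not in herbs:
            herbs.append(row["herb"])
        ingredients.append(
            Ingredient(
                row["mol_id"], row["name"],
                _num(path, i, "ob", row["ob"]), _num(path, i, "dl", row["dl"]),
                row["herb"],
            )
        )
    return Formulary(tuple(herbs), tuple(ingredients))


def write_ingredient_table(formulary: Formulary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("mol_id\tname\tob\tdl\therb\n")
        for i in formulary.ingredients:
            fh.write(f"{i.mol_id}\t{i.name}\t{i.ob:g}\t{i.dl:g}\t{i.herb}\n")


def write_screen_summary(counts: dict[str, int], path: str | Path) -> None:
    """One-line JSON summary of the retained-ingredient counts per herb."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump({"retained_per_herb": counts, "retained_total": sum(counts.values())},
                  fh, sort_keys=True)
        fh.write("\n")


def read_compound_target_map(path: str | Path) -> CompoundTargetMap:
    df = _read_tsv(path, ["mol_id", "herb", "target"])
    return CompoundTargetMap.from_raw(
        (row["mol_id"], row["herb"], row["target"]) for _, row in df.iterrows()
    )


def write_compound_target_map(ct_map: CompoundTargetMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("mol_id\therb\ttarget\n")
        for mol, herb, tgt in ct_map.edges:
            fh.write(f"{mol}\t{herb}\t{tgt}\n")


def read_disease_table(path: str | Path) -> list[DiseaseTargetRecord]:
    path = Path(path)
    df = _read_tsv(path, ["symbol", "score", "source"])
    out = []
    for i, row in df.iterrows():
        score = None if row["score"] == "" else _num(path, i, "score", row["score"])
        out.append(DiseaseTargetRecord(row["symbol"], score, row["source"]))
    return out


def write_disease_table(records: Sequence[DiseaseTargetRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("symbol\tscore\tsource\n")
        for r in records:
            score = "" if r.score is None else f"{r.score:g}"
            fh.write(f"{r.symbol}\t{score}\t{r.source}\n")


def read_edge_table(path: str | Path) -> list[ScoredEdge]:
    path = Path(path)
    df = _read_tsv(path, ["protein_a", "protein_b"])
    has_score = "score" in df.columns
    out = []
    for i, row in df.iterrows():
        score = None
        if has_score and row["score"] != "":
            score = _num(path, i, "score", row["score"])
        out.append(ScoredEdge(row["protein_a"], row["protein_b"], score))
    return out


def write_edge_table(edges: Sequence[ScoredEdge], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein_a\tprotein_b\tscore\n")
        for e in edges:
            score = "" if e.score is None else f"{e.score:g}"
            fh.write(f"{e.a}\t{e.b}\t{score}\n")


def read_gene_list(path: str | Path, label: Optional[str] = None) -> GeneSet:
    """Plain-text gene list, one symbol per line; blank lines ignored."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        syms = [line.strip() for line in fh]
    return GeneSet.from_raw(label or path.stem, (s for s in syms if s))


def write_gene_list(genes: GeneSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in sorted(genes.symbols):
            fh.write(s + "\n")


def read_gmt(path: str | Path, categories: Optional[dict[str, str]] = None) -> TermDB:
    """Standard GMT: term id, description, then member symbols.

    ``categories`` optionally maps term id → category label (the sidecar
    produced alongside multi-database exports); unmapped terms get "".
    """
    path = Path(path)
    terms = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}: line {ln}: GMT rows need term, description, >=1 member"
                )
            tid, desc = parts[0], parts[1]
            members = frozenset(normalize_symbol(s) for s in parts[2:] if s.strip())
            if not members:
                raise ValidationError(f"{path}: line {ln}: term {tid!r} has no members")
            cat = (categories or {}).get(tid, "")
            terms.append((tid, cat, desc, members))
    return TermDB(tuple(terms))


def write_gmt(db: TermDB, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for tid, _, desc, members in db.terms:
            fh.write("\t".join([tid, desc, *sorted(members)]) + "\n")


def read_category_sidecar(path: str | Path) -> dict[str, str]:
    df = _read_tsv(path, ["term_id", "category"])
    return dict(zip(df["term_id"], df["category"]))


def read_centrality_table(path: str | Path) -> list[CentralityRecord]:
    path = Path(path)
    df = _read_tsv(path, ["symbol", "degree", "closeness"])
    out = []
    for i, row in df.iterrows():
        hub = row.get("is_hub", "False") in ("True", "true", "1")
        out.append(
            CentralityRecord(
                row["symbol"],
                int(_num(path, i, "degree", row["degree"])),
                _num(path, i, "closeness", row["closeness"]),
                hub,
            )
        )
    return out


def write_centrality_table(records: Sequence[CentralityRecord], path: str | Path) -> None:
    """Centrality TSV; closeness printed with 5 decimals."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("symbol\tdegree\tcloseness\tis_hub\n")
        for r in records:
            fh.write(f"{r.symbol}\t{r.degree}\t{r.closeness:.5f}\t{r.is_hub}\n")


def write_enrichment_table(terms: Sequence[EnrichmentTerm], path: str | Path) -> None:
    """Enriched-term TSV; log values to 2 decimals."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("term_id\tcategory\tdescription\tcount\tpercent\tlog10_p\t"
                 "log10_q\tenrichment_factor\tcluster_id\n")
        for t in terms:
            cid = "" if t.cluster_id is None else str(t.cluster_id)
            fh.write(
                f"{t.term_id}\t{t.category}\t{t.description}\t{t.k}\t"
                f"{t.percent:.2f}\t{t.log10_p:.2f}\t{t.log10_q:.2f}\t"
                f"{t.enrichment_factor:.4g}\t{cid}\n"
            )
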