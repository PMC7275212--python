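"""Synthetic input generators with planted ground truth.

Every file the pipeline consumes can be generated here, with bookkept
ground truth (which ADME records pass, which genes overlap the disease
set, which annotation terms are enriched), so every stage is testable
end-to-end without any external database export.

Gene symbols are drawn from an artificial universe (``G000001`` …);
no real gene symbols appear, making explicit that no biological claim
is emulated — only the statistical shape of the inputs: OB/DL values
straddling the screening thresholds, heavy-tailed per-compound target
counts, a disease list with a controlled overlap against the herb
targets, a random PPI graph over the key targets, and a term database
with planted over-represented terms among uniform decoys.

One integer seed drives everything; each generator derives its own
sub-stream by stable hashing of its name, so adding a generator later
cannot shift the outputs of earlier ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .formulary import Formulary, Ingredient, ValidationError
from .metrics import ScoredEdge
from .network import CompoundTargetMap
from .targets import DiseaseTargetRecord, GeneSet, GENECARDS_LIKE, OMIM_LIKE
from .enrichment import TermDB

OB_THRESHOLD = 33.0
DL_THRESHOLD = 0.18


def subseed(seed: int, name: str) -> int:
    """Stable per-generator sub-seed below 2**31."""
    h = hashlib.sha256(f"{name}:{seed}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(subseed(seed, name))


@dataclass(frozen=True)
class SynthesisConfig:
    """Knobs of the synthetic study; defaults mirror the target scale
    (3 herbs, ~15 ingredients each, an ~80-node PPI)."""

    seed: int = 0
    n_herbs: int = 3
    ingredients_per_herb: int = 15
    adme_pass_fraction: float = 0.5
    targets_per_ingredient_mean: float = 8.0
    gene_universe_size: int = 300
    disease_set_size: int = 150
    herb_disease_overlap: float = 0.5
    disease_score_pass_fraction: float = 0.8
    ppi_model: str = "erdos_renyi"
    ppi_params: dict = field(default_factory=dict)
    n_terms: int = 50
    term_universe_size: int = 2000
    term_size_range: tuple[int, int] = (5, 20)
    planted_terms: tuple[tuple[int, int], ...] = ((20, 40),)

    def __post_init__(self) -> None:
        if min(self.n_herbs, self.ingredients_per_herb, self.gene_universe_size,
               self.disease_set_size, self.term_universe_size) < 1:
            raise ValidationError("all synthesis counts must be >= 1")
        for f in ("adme_pass_fraction", "herb_disease_overlap",
                  "disease_score_pass_fraction"):
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{f} must lie in [0, 1], got {v!r}")
        if self.targets_per_ingredient_mean < 1:
            raise ValidationError("targets_per_ingredient_mean must be >= 1")
        if self.ppi_model not in ("erdos_renyi", "barabasi_albert"):
            raise ValidationError(f"unknown ppi_model {self.ppi_model!r}")


def gene_symbol(i: int) -> str:
    return f"G{i:06d}"


def gen_formulary(cfg: SynthesisConfig) -> tuple[Formulary, list[tuple[str, str]]]:
    """Ingredient tables with a planted ADME pass set.

    Passers draw OB ~ U[33, 110] and DL ~ U[0.18, 0.95]; failers violate
    at least one threshold.  Returns the formulary and the ground-truth
    list of passing (mol_id, herb) pairs; exactly
    round(pass_fraction · n) records pass per herb.
    """
    rng = _rng(cfg.seed, "formulary")
    herbs = tuple(f"Herb{h+1:02d}" for h in range(cfg.n_herbs))
    ingredients: list[Ingredient] = []
    passers: list[tuple[str, str]] = []
    mol_counter = 0
    for herb in herbs:
        n = cfg.ingredients_per_herb
        n_pass = int(round(cfg.adme_pass_fraction * n))
        pass_idx = set(rng.permutation(n)[:n_pass].tolist())
        for i in range(n):
            mol_counter += 1
            mol = f"SYN{mol_counter:06d}"
            if i in pass_idx:
                ob = float(rng.uniform(OB_THRESHOLD, 110.0))
                dl = float(rng.uniform(DL_THRESHOLD, 0.95))
                passers.append((mol, herb))
            else:
                mode = rng.integers(0, 3)  # 0: fail OB, 1: fail DL, 2: fail both
                if mode == 0:
                    ob = float(rng.uniform(0.0, OB_THRESHOLD * 0.999))
                    dl = float(rng.uniform(DL_THRESHOLD, 0.95))
                elif mode == 1:
                    ob = float(rng.uniform(OB_THRESHOLD, 110.0))
                    dl = float(rng.uniform(0.0, DL_THRESHOLD * 0.999))
                else:
                    ob = float(rng.uniform(0.0, OB_THRESHOLD * 0.999))
                    dl = float(rng.uniform(0.0, DL_THRESHOLD * 0.999))
            ingredients.append(Ingredient(mol, f"compound-{mol}", round(ob, 2),
                                          round(dl, 4), herb))
    return Formulary(herbs, tuple(ingredients)), passers


def gen_compound_target_map(
    cfg: SynthesisConfig, formulary: Formulary
) -> CompoundTargetMap:
    """Bipartite compound→target edges with heavy-tailed target counts.

    Per-ingredient counts are geometric (support {1, 2, …}) with the
    configured mean, emulating the few-compounds-hit-many-targets shape
    of curated compound-target exports; targets are sampled without
    replacement from the synthetic gene universe.
    """
    if not formulary.ingredients:
        raise ValidationError("formulary is empty")
    rng = _rng(cfg.seed, "compound_target_map")
    p = 1.0 / cfg.targets_per_ingredient_mean
    triples: list[tuple[str, str, str]] = []
    for ing in formulary.ingredients:
        count = min(int(rng.geometric(p)), cfg.gene_universe_size)
        idx = rng.choice(cfg.gene_universe_size, size=count, replace=False)
        for g in sorted(int(i) for i in idx):
            triples.append((ing.mol_id, ing.herb, gene_symbol(g)))
    return CompoundTargetMap(tuple(triples))


def gen_disease_and_ppi(
    cfg: SynthesisConfig, herb_targets: GeneSet
) -> tuple[list[DiseaseTargetRecord], list[ScoredEdge], dict]:
    """Disease-target records and a PPI edge list over the planted overlap.

    The disease list contains floor(overlap · |herb targets|) planted
    herb-target genes — all passing the functionality-score filter — plus
    filler genes outside the herb-target universe, a configured fraction
    of which pass.  The PPI is generated over the planted key targets by
    the configured random-graph model with confidence scores ~ U[0, 1].
    Returns (records, edges, ground_truth).
    """
    if not herb_targets.symbols:
        raise ValidationError("herb target universe is empty")
    rng = _rng(cfg.seed, "disease_and_ppi")
    herb_syms = sorted(herb_targets.symbols)
    n_overlap = int(np.floor(cfg.herb_disease_overlap * len(herb_syms)))
    overlap = sorted(
        herb_syms[int(i)] for i in rng.choice(len(herb_syms), n_overlap, replace=False)
    )
    records: list[DiseaseTargetRecord] = []
    for g in overlap:
        if rng.random() < 0.2:  # some planted genes arrive via the unscored source
            records.append(DiseaseTargetRecord(g, None, OMIM_LIKE))
        else:
            records.append(DiseaseTargetRecord(g, float(round(rng.uniform(30, 100), 1)),
                                               GENECARDS_LIKE))
    n_fill = max(cfg.disease_set_size - n_overlap, 0)
    for j in range(n_fill):
        g = f"D{j:06d}"  # outside the herb-target universe by construction
        if rng.random() < cfg.disease_score_pass_fraction:
            score = float(round(rng.uniform(30, 100), 1))
        else:
            score = float(round(rng.uniform(0, 29.9), 1))
        records.append(DiseaseTargetRecord(g, score, GENECARDS_LIKE))

    edges = gen_ppi_edges(cfg, overlap, rng)
    truth = {
        "planted_overlap": overlap,
        "n_overlap": n_overlap,
        "ppi_nodes": len(overlap),
        "ppi_edges": len(edges),
    }
    return records, edges, truth


def gen_ppi_edges(
    cfg: SynthesisConfig, nodes: Sequence[str], rng: Optional[np.random.Generator] = None
) -> list[ScoredEdge]:
    """Random-graph edge list (Erdős–Rényi or Barabási–Albert) with
    uniform confidence scores."""
    import networkx as nx

    if rng is None:
        rng = _rng(cfg.seed, "ppi")
    n = len(nodes)
    gseed = int(rng.integers(0, 2**31))
    if cfg.ppi_model == "erdos_renyi":
        # default p gives the target-scale expectation: ~729 edges on 83 nodes
        p = cfg.ppi_params.get("p", 2 * 729 / (83 * 82))
        g = nx.gnp_random_graph(n, p, seed=gseed)
    else:
        m = cfg.ppi_params.get("m", 3)
        g = nx.barabasi_albert_graph(n, min(m, max(n - 1, 1)), seed=gseed)
    edges = []
    for a, b in sorted(g.edges()):
        edges.append(ScoredEdge(nodes[a], nodes[b], float(round(rng.uniform(), 3))))
    return edges


def gen_term_db(
    cfg: SynthesisConfig, key_targets: GeneSet
) -> tuple[TermDB, list[str]]:
    """Term database with planted over-represented terms among decoys.

    Each planted (subset_size, term_size) pair yields a term containing
    ``subset_size`` genes from ``key_targets`` padded with background
    fillers to ``term_size``; decoy terms draw uniformly from a disjoint
    background universe.  Returns (db, planted term ids).
    """
    if not key_targets.symbols:
        raise ValidationError("key-target set is empty")
    rng = _rng(cfg.seed, "term_db")
    keys = sorted(key_targets.symbols)
    bg = [f"B{i:06d}" for i in range(cfg.term_universe_size)]
    terms: list[tuple[str, str, str, frozenset[str]]] = []
    planted_ids: list[str] = []
    for t, (subset_size, term_size) in enumerate(cfg.planted_terms):
        if subset_size > len(keys):
            raise ValidationError(
                f"planted subset of {subset_size} exceeds key-target set of {len(keys)}"
            )
        picked = [keys[int(i)] for i in rng.choice(len(keys), subset_size, replace=False)]
        n_fill = max(term_size - subset_size, 0)
        fill = [bg[int(i)] for i in rng.choice(len(bg), n_fill, replace=False)]
        tid = f"PLANT{t:04d}"
        planted_ids.append(tid)
        terms.append((tid, "synthetic planted", f"planted term {t}",
                      frozenset(picked + fill)))
    lo, hi = cfg.term_size_range
    for t in range(cfg.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(bg[int(i)] for i in rng.choice(len(bg), size, replace=False))
        terms.append((f"DECOY{t:04d}", "synthetic decoy", f"decoy term {t}", members))
    return TermDB(tuple(terms)), planted_ids


def write_bundle(cfg: SynthesisConfig, out_dir: str | Path) -> dict:
    """Generate and write the full synthetic input bundle.

    Writes ingredient TSV, compound-target TSV, disease TSV, PPI edge
    TSV, term GMT and a ground-truth JSON into ``out_dir``; returns the
    ground-truth dict.  Byte-identical for identical configs.
    """
    from . import io as npio
    from .formulary import screen_ingredients, per_herb_counts
    from .targets import herb_target_union

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    formulary, passers = gen_formulary(cfg)
    npio.write_ingredient_table(formulary, out / "ingredients.tsv")

    screened = screen_ingredients(formulary)
    ct_map = gen_compound_target_map(cfg, screened)
    npio.write_compound_target_map(ct_map, out / "compound_targets.tsv")

    herb_union = GeneSet("herbs", frozenset(t for _, _, t in ct_map.edges))
    records, edges, ppi_truth = gen_disease_and_ppi(cfg, herb_union)
    npio.write_disease_table(records, out / "disease_targets.tsv")
    npio.write_edge_table(edges, out / "ppi_edges.tsv")

    key = GeneSet("key", frozenset(ppi_truth["planted_overlap"]))
    db, planted_ids = gen_term_db(cfg, key)
    npio.write_gmt(db, out / "terms.gmt")

    truth = {
        "config": {**asdict(cfg), "planted_terms": [list(t) for t in cfg.planted_terms]},
        "adme_pass_pairs": [list(p) for p in passers],
        "adme_pass_counts": per_herb_counts(screened),
        "herb_target_counts": {
            h: len(herb_target_union(ct_map.edges, h))
            for h in formulary.herbs
            if any(e[1] == h for e in ct_map.edges)
        },
        "planted_overlap": ppi_truth["planted_overlap"],
        "ppi_nodes": ppi_truth["ppi_nodes"],
        "ppi_edges": ppi_truth["ppi_edges"],
        "planted_term_ids": planted_ids,
    }
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
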