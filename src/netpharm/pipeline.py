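"""End-to-end pipeline driver: files in, files out, one summary JSON.

Each stage is a pure function of its input files; rerunning the
pipeline on identical inputs and configuration produces byte-identical
artifacts.  Any stage failure aborts with the stage name.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import io as npio
from .enrichment import (DEFAULT_KAPPA_MIN, DEFAULT_MIN_COUNT, DEFAULT_MIN_FACTOR,
                         DEFAULT_P_MAX, enrich, kappa_cluster)
from .formulary import (DEFAULT_DL_MIN, DEFAULT_OB_MIN, ValidationError,
                        per_herb_counts, screen_ingredients)
from .metrics import (DEFAULT_CLOSENESS_MIN, DEFAULT_DEGREE_MIN,
                      DEFAULT_EDGE_SCORE_MIN, average_degree, build_graph,
                      centrality_table, filter_edges_by_confidence, screen_hubs)
from .network import build_network, export_cytoscape, network_summary
from .targets import (DEFAULT_GIFTS_MIN, GeneSet, filter_disease_targets,
                      herb_target_union, merge_disease_sources, venn3)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input/output paths plus every threshold the stages consume.

    Threshold defaults are the conventional ones for this kind of
    screen: OB >= 33 %, DL >= 0.18, functionality score >= 30, edge
    confidence >= 0.4, hub degree >= 20 and closeness >= 48.33,
    enrichment p < 0.01 with count >= 3 and factor > 1.5, and kappa
    linkage at 0.3.
    """

    ingredients: str = "ingredients.tsv"
    compound_targets: str = "compound_targets.tsv"
    disease_targets: str = "disease_targets.tsv"
    disease_targets_extra: Optional[str] = None
    ppi_edges: str = "ppi_edges.tsv"
    terms_gmt: str = "terms.gmt"
    term_categories: Optional[str] = None
    out_dir: str = "results"
    disease_label: str = "disease"

    ob_min: float = DEFAULT_OB_MIN
    dl_min: float = DEFAULT_DL_MIN
    gifts_min: float = DEFAULT_GIFTS_MIN
    edge_score_min: float = DEFAULT_EDGE_SCORE_MIN
    deg_min: int = DEFAULT_DEGREE_MIN
    clo_min: float = DEFAULT_CLOSENESS_MIN
    p_max: float = DEFAULT_P_MAX
    min_count: int = DEFAULT_MIN_COUNT
    min_factor: float = DEFAULT_MIN_FACTOR
    kappa_min: float = DEFAULT_KAPPA_MIN

    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline aborted at stage {stage!r}: {cause}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run screen → targets → venn → network → ppi → hubs → enrich.

    Writes each stage's artifact under ``cfg.out_dir`` and returns the
    machine-readable run summary (also written as ``summary.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"thresholds": {
        k: getattr(cfg, k)
        for k in ("ob_min", "dl_min", "gifts_min", "edge_score_min", "deg_min",
                  "clo_min", "p_max", "min_count", "min_factor", "kappa_min")
    }, "seed": cfg.seed}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                log.error("stage %s failed: %s", name, exc)
                (out / "INCOMPLETE").write_text(f"failed at stage {name}: {exc}\n")
                raise StageError(name, exc) from exc
        return deco

    @stage("screen")
    def screened():
        formulary = npio.read_ingredient_table(cfg.ingredients)
        kept = screen_ingredients(formulary, cfg.ob_min, cfg.dl_min)
        npio.write_ingredient_table(kept, out / "screened_ingredients.tsv")
        counts = per_herb_counts(kept)
        npio.write_screen_summary(counts, out / "screen_summary.json")
        summary["screen"] = {"input": len(formulary), "retained": len(kept),
                             "per_herb": counts}
        return kept

    @stage("targets")
    def target_stage():
        ct_map = npio.read_compound_target_map(cfg.compound_targets)
        screened_pairs = {(i.mol_id, i.herb) for i in screened.ingredients}
        ct_map = type(ct_map)(tuple(e for e in ct_map.edges
                                    if (e[0], e[1]) in screened_pairs))
        herb_sets = {}
        for h in screened.herbs:
            if any(e[1] == h for e in ct_map.edges):
                herb_sets[h] = herb_target_union(ct_map.edges, h)
        records = npio.read_disease_table(cfg.disease_targets)
        disease = filter_disease_targets(records, cfg.gifts_min, cfg.disease_label)
        if cfg.disease_targets_extra:
            extra = filter_disease_targets(
                npio.read_disease_table(cfg.disease_targets_extra),
                cfg.gifts_min, cfg.disease_label)
            disease = merge_disease_sources(disease, extra, cfg.disease_label)
        npio.write_gene_list(disease, out / "disease_genes.txt")
        summary["targets"] = {"per_herb": {h: len(s) for h, s in herb_sets.items()},
                              "disease": len(disease)}
        return ct_map, herb_sets, disease

    ct_map, herb_sets, disease = target_stage

    @stage("venn")
    def venn_stage():
        if not disease.symbols:
            raise ValidationError("disease-target set is empty after filtering")
        report = venn3(herb_sets, disease)
        if not report.key_targets.symbols:
            raise ValidationError("no key targets: herb and disease sets are disjoint")
        with open(out / "venn_report.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump({"per_herb_counts": report.per_herb_counts,
                       "key_targets": sorted(report.key_targets.symbols)},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")
        npio.write_gene_list(report.key_targets, out / "key_targets.txt")
        summary["venn"] = {"per_herb": report.per_herb_counts,
                           "key_targets": len(report.key_targets)}
        return report

    @stage("network")
    def network_stage():
        net = build_network(cfg.disease_label, screened, ct_map, venn_stage.key_targets)
        export_cytoscape(net, out / "tetrapartite")
        summary["network"] = network_summary(net)
        return net

    @stage("ppi")
    def ppi_stage():
        edges = npio.read_edge_table(cfg.ppi_edges)
        kept = filter_edges_by_confidence(edges, cfg.edge_score_min)
        g = build_graph(kept, venn_stage.key_targets)
        summary["ppi"] = {"nodes": g.number_of_nodes(), "edges": g.number_of_edges(),
                          "average_degree": round(average_degree(g), 1)}
        return g

    @stage("hubs")
    def hub_stage():
        records = centrality_table(ppi_stage)
        hubs = screen_hubs(records, cfg.deg_min, cfg.clo_min)
        hub_syms = {h.symbol for h in hubs}
        records = [type(r)(r.symbol, r.degree, r.closeness, r.symbol in hub_syms)
                   for r in records]
        npio.write_centrality_table(records, out / "centralities.tsv")
        hub_set = GeneSet("hubs", frozenset(hub_syms))
        npio.write_gene_list(hub_set, out / "hub_genes.txt")
        summary["hubs"] = {"n_hubs": len(hubs)}
        return hub_set

    @stage("enrich")
    def enrich_stage():
        cats = (npio.read_category_sidecar(cfg.term_categories)
                if cfg.term_categories else None)
        db = npio.read_gmt(cfg.terms_gmt, cats)
        if not hub_stage.symbols:
            log.warning("hub list is empty; writing empty enrichment table")
            npio.write_enrichment_table([], out / "enriched_terms.tsv")
            summary["enrich"] = {"n_terms": 0, "n_clusters": 0, "skipped": "no hubs"}
            return []
        if not (hub_stage.symbols & db.universe()):
            log.warning("no hub gene is annotated in the term database; "
                        "writing empty enrichment table")
            npio.write_enrichment_table([], out / "enriched_terms.tsv")
            summary["enrich"] = {"n_terms": 0, "n_clusters": 0,
                                 "skipped": "hubs unannotated"}
            return []
        terms = enrich(hub_stage, db, "auto", cfg.p_max, cfg.min_count, cfg.min_factor)
        if terms:
            terms = kappa_cluster(terms, db, hub_stage, cfg.kappa_min)
        npio.write_enrichment_table(terms, out / "enriched_terms.tsv")
        summary["enrich"] = {"n_terms": len(terms),
                             "n_clusters": len({t.cluster_id for t in terms})}
        return terms

    _ = enrich_stage
    with open(out / "summary.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    incomplete = out / "INCOMPLETE"
    if incomplete.exists():
        incomplete.unlink()
    return summary
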