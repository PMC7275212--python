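"""Disease–drug–ingredient–target network assembly and export.

The tetrapartite network links one disease node to the formula's drug
(herb) nodes, each drug to its active ingredients, and each ingredient to
its key targets.  Ingredients whose targets are disjoint from the key
targets are pruned — they connect the formula to nothing disease-relevant
— which is what shrinks a screened ingredient list down to the subset
appearing in the final network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .formulary import Formulary, ValidationError
from .targets import GeneSet, normalize_symbol

NODE_CLASSES = ("disease", "drug", "ingredient", "target")
# allowed undirected class pairs and the SIF interaction label for each
EDGE_LABELS = {
    frozenset({"disease", "drug"}): "treats",
    frozenset({"drug", "ingredient"}): "contains",
    frozenset({"ingredient", "target"}): "targets",
}


@dataclass(frozen=True)
class CompoundTargetMap:
    """Bipartite compound→target relation as (mol_id, herb, symbol) triples."""

    edges: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            if e in seen:
                raise ValidationError(f"duplicate compound-target triple {e}")
            seen.add(e)

    @classmethod
    def from_raw(cls, triples: Iterable[tuple[str, str, str]]) -> "CompoundTargetMap":
        out, seen = [], set()
        for mol, herb, sym in triples:
            t = (mol, herb, normalize_symbol(sym))
            if t not in seen:
                seen.add(t)
                out.append(t)
        return cls(tuple(out))

    def targets_of(self, mol_id: str) -> frozenset[str]:
        return frozenset(t for m, _, t in self.edges if m == mol_id)


@dataclass(frozen=True)
class TetrapartiteNetwork:
    """Typed node records plus undirected class-respecting edges."""

    nodes: tuple[tuple[str, str], ...]  # (node id, node class)
    edges: tuple[tuple[str, str], ...]  # (source id, target id)
    labels: dict[str, str] = field(default_factory=dict)  # node id -> display label

    def node_class(self, node_id: str) -> str:
        for nid, cls in self.nodes:
            if nid == node_id:
                return cls
        raise KeyError(node_id)


def build_network(
    disease: str,
    formulary: Formulary,
    ct_map: CompoundTargetMap,
    key_targets: GeneSet,
) -> TetrapartiteNetwork:
    """Assemble the pruned disease–drug–ingredient–target network.

    Ingredient nodes are restricted to ingredients with at least one
    target in ``key_targets``; target nodes to key targets reachable
    through a retained ingredient.  A molecule listed under two herbs
    becomes a single ingredient node with an edge to both drug nodes.
    """
    if not key_targets.symbols:
        raise ValidationError("key_targets must be non-empty")
    known_pairs = {(i.mol_id, i.herb) for i in formulary.ingredients}
    for mol, herb, _ in ct_map.edges:
        if (mol, herb) not in known_pairs:
            raise ValidationError(
                f"compound-target map references ({mol}, {herb}) absent from formulary"
            )

    # mol_id -> set of key targets it hits; mol_id -> herbs listing it
    hits: dict[str, set[str]] = {}
    herbs_of: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for ing in formulary.ingredients:
        herbs_of.setdefault(ing.mol_id, set()).add(ing.herb)
        names.setdefault(ing.mol_id, ing.name)
    for mol, _, tgt in ct_map.edges:
        if tgt in key_targets:
            hits.setdefault(mol, set()).add(tgt)

    retained = sorted(m for m in hits if m in herbs_of)
    retained_targets = sorted(set().union(*(hits[m] for m in retained)) if retained else set())
    retained_herbs = [h for h in formulary.herbs]

    nodes: list[tuple[str, str]] = [(disease, "disease")]
    nodes += [(h, "drug") for h in retained_herbs]
    nodes += [(m, "ingredient") for m in retained]
    nodes += [(t, "target") for t in retained_targets]
    ids = [n for n, _ in nodes]
    if len(set(ids)) != len(ids):
        raise ValidationError("node id collision across classes")

    edges: list[tuple[str, str]] = [(disease, h) for h in retained_herbs]
    for m in retained:
        for h in sorted(herbs_of[m]):
            edges.append((h, m))
        for t in sorted(hits[m]):
            edges.append((m, t))

    labels = {disease: disease}
    labels.update({h: h for h in retained_herbs})
    labels.update({m: names[m] for m in retained})
    labels.update({t: t for t in retained_targets})
    return TetrapartiteNetwork(tuple(nodes), tuple(edges), labels)


def network_summary(net: TetrapartiteNetwork) -> dict[str, int]:
    """Node counts per class plus the total edge count."""
    out = {c: 0 for c in NODE_CLASSES}
    for _, cls in net.nodes:
        out[cls] += 1
    out["edges"] = len(net.edges)
    return out


def export_cytoscape(net: TetrapartiteNetwork, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write a SIF edge file and a node-attribute TSV.

    SIF lines are ``source<TAB>interaction<TAB>target`` with interaction
    labels ``treats`` / ``contains`` / ``targets``; the attribute file
    maps node id to class and display label.  Returns the two paths.
    """
    prefix = Path(out_prefix)
    sif_path = prefix.with_suffix(".sif")
    attr_path = Path(str(prefix) + "_nodes.tsv")
    cls = dict(net.nodes)
    try:
        with open(sif_path, "w", encoding="utf-8", newline="\n") as fh:
            for a, b in net.edges:
                label = EDGE_LABELS[frozenset({cls[a], cls[b]})]
                fh.write(f"{a}\t{label}\t{b}\n")
        with open(attr_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("node_id\tclass\tlabel\n")
            for nid, c in net.nodes:
                fh.write(f"{nid}\t{c}\t{net.labels.get(nid, nid)}\n")
    except OSError as exc:
        raise OSError(f"failed writing network export near {prefix}: {exc}") from exc
    return sif_path, attr_path


def read_cytoscape(sif_path: str | Path, attr_path: str | Path) -> TetrapartiteNetwork:
    """Round-trip reader for :func:`export_cytoscape` output."""
    nodes: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    with open(attr_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header != ["node_id", "class", "label"]:
            raise ValidationError(f"{attr_path}: unexpected attribute header {header}")
        for line in fh:
            nid, c, label = line.rstrip("\r\n").split("\t")
            nodes.append((nid, c))
            labels[nid] = label
    edges: list[tuple[str, str]] = []
    with open(sif_path, encoding="utf-8") as fh:
        for line in fh:
            a, _, b = line.rstrip("\r\n").split("\t")
            edges.append((a, b))
    return TetrapartiteNetwork(tuple(nodes), tuple(edges), labels)


def to_graphml(net: TetrapartiteNetwork, path: str | Path) -> None:
    """Optional GraphML export carrying the same node attributes."""
    g = nx.Graph()
    for nid, cls in net.nodes:
        g.add_node(nid, node_class=cls, label=net.labels.get(nid, nid))
    g.add_edges_from(net.edges)
    nx.write_graphml(g, path)
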