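"""Tetrapartite network assembly, pruning and Cytoscape export."""

import pytest

from netpharm import (CompoundTargetMap, Formulary, GeneSet, Ingredient,
                      ValidationError, build_network, export_cytoscape,
                      network_summary, read_cytoscape, screen_ingredients)
from netpharm.io import read_compound_target_map, read_gene_list
from netpharm.network import to_graphml


def minimal_inputs():
    formulary = Formulary(("HerbA",), (Ingredient("M1", "alpha", 50, 0.5, "HerbA"),))
    ct_map = CompoundTargetMap((("M1", "HerbA", "A"),))
    return formulary, ct_map


def test_minimal_chain():
    formulary, ct_map = minimal_inputs()
    net = build_network("dis", formulary, ct_map, GeneSet("k", frozenset({"A"})))
    assert network_summary(net) == {"disease": 1, "drug": 1, "ingredient": 1,
                                    "target": 1, "edges": 3}


def test_ingredient_without_key_target_pruned():
    formulary = Formulary(("HerbA",), (Ingredient("M1", "a", 50, 0.5, "HerbA"),
                                       Ingredient("M2", "b", 50, 0.5, "HerbA")))
    ct_map = CompoundTargetMap((("M1", "HerbA", "A"), ("M1", "HerbA", "B"),
                                ("M2", "HerbA", "C")))
    net = build_network("dis", formulary, ct_map, GeneSet("k", frozenset({"C"})))
    classes = dict(net.nodes)
    assert "M2" in classes and "M1" not in classes
    assert classes["C"] == "target" and "A" not in classes


def test_shared_molecule_single_node_two_drug_edges():
    formulary = Formulary(("H1", "H2"), (Ingredient("M1", "a", 50, 0.5, "H1"),
                                         Ingredient("M1", "a", 50, 0.5, "H2")))
    ct_map = CompoundTargetMap((("M1", "H1", "A"), ("M1", "H2", "A")))
    net = build_network("dis", formulary, ct_map, GeneSet("k", frozenset({"A"})))
    assert network_summary(net) == {"disease": 1, "drug": 2, "ingredient": 1,
                                    "target": 1, "edges": 5}
    assert sum(1 for a, b in net.edges if b == "M1") == 2


def test_map_ingredient_missing_from_formulary_rejected():
    formulary, _ = minimal_inputs()
    bad = CompoundTargetMap((("M9", "HerbA", "A"),))
    with pytest.raises(ValidationError, match="M9"):
        build_network("dis", formulary, bad, GeneSet("k", frozenset({"A"})))


def test_empty_key_targets_rejected():
    formulary, ct_map = minimal_inputs()
    with pytest.raises(ValidationError):
        build_network("dis", formulary, ct_map, GeneSet("k", frozenset()))


def test_pruning_is_a_fixpoint():
    formulary = Formulary(("H",), (Ingredient("M1", "a", 50, 0.5, "H"),
                                   Ingredient("M2", "b", 50, 0.5, "H")))
    ct_map = CompoundTargetMap((("M1", "H", "A"), ("M2", "H", "B")))
    key = GeneSet("k", frozenset({"A"}))
    net1 = build_network("dis", formulary, ct_map, key)
    retained = {nid for nid, cls in net1.nodes if cls == "ingredient"}
    formulary2 = Formulary(formulary.herbs, tuple(
        i for i in formulary.ingredients if i.mol_id in retained))
    ct_map2 = CompoundTargetMap(tuple(e for e in ct_map.edges if e[0] in retained))
    net2 = build_network("dis", formulary2, ct_map2, key)
    assert set(net1.nodes) == set(net2.nodes)
    assert sorted(net1.edges) == sorted(net2.edges)


def test_counts_invariant_under_input_row_order():
    formulary = Formulary(("H",), (Ingredient("M1", "a", 50, 0.5, "H"),
                                   Ingredient("M2", "b", 50, 0.5, "H")))
    key = GeneSet("k", frozenset({"A", "B"}))
    edges = (("M1", "H", "A"), ("M2", "H", "B"), ("M2", "H", "A"))
    s1 = network_summary(build_network("d", formulary, CompoundTargetMap(edges), key))
    s2 = network_summary(build_network("d", formulary,
                                       CompoundTargetMap(edges[::-1]), key))
    assert s1 == s2


def test_synthetic_surviving_ingredient_count(synthetic_bundle):
    """Exactly the ingredients with >= 1 key target survive the pruning."""
    out, _, truth = synthetic_bundle
    ct_map = read_compound_target_map(out / "compound_targets.tsv")
    from netpharm.io import read_ingredient_table
    screened = screen_ingredients(read_ingredient_table(out / "ingredients.tsv"))
    key = GeneSet("k", frozenset(truth["planted_overlap"]))
    expected = {m for m, _, t in ct_map.edges if t in key}
    net = build_network("dis", screened, ct_map, key)
    assert {nid for nid, cls in net.nodes if cls == "ingredient"} == expected
    for m in sorted(expected):
        hit = {b for a, b in net.edges if a == m} | {a for a, b in net.edges
                                                     if b == m and a in key}
        assert hit & key.symbols  # every retained ingredient keeps a key edge


def test_sif_round_trip(tmp_path):
    formulary = Formulary(("H1", "H2"), (Ingredient("M1", "a", 50, 0.5, "H1"),
                                         Ingredient("M1", "a", 50, 0.5, "H2"),
                                         Ingredient("M2", "b", 50, 0.5, "H1")))
    ct_map = CompoundTargetMap((("M1", "H1", "A"), ("M1", "H2", "B"),
                                ("M2", "H1", "A")))
    net = build_network("dis", formulary, ct_map, GeneSet("k", frozenset({"A", "B"})))
    sif, attrs = export_cytoscape(net, tmp_path / "net")
    back = read_cytoscape(sif, attrs)
    assert set(back.nodes) == set(net.nodes)
    assert sorted(back.edges) == sorted(net.edges)
    assert back.labels == net.labels
    to_graphml(net, tmp_path / "net.graphml")  # exporter writes without error


def test_sif_interaction_labels(tmp_path):
    formulary, ct_map = minimal_inputs()
    net = build_network("dis", formulary, ct_map, GeneSet("k", frozenset({"A"})))
    sif, _ = export_cytoscape(net, tmp_path / "net")
    labels = {line.split("\t")[1] for line in sif.read_text().splitlines()}
    assert labels == {"treats", "contains", "targets"}
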