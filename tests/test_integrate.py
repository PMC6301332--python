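import random
from decimal import Decimal

import pytest

from annalign.docmodel import Document, Entity, Relation
from annalign.integrate import (
    IdMappingTable,
    NerAnnotation,
    apply_id_mapping,
    build_network,
    corpus_stats,
    corpus_stats_from_counts,
    merge_documents,
    normalize_entities,
    parse_pubtator,
)


def _doc(doc_id="d1", text="x" * 40):
    return Document(doc_id=doc_id, text=text)


def _ent(key, start, end, text, etype="gene", tool="t", norm_ids=None):
    return Entity(
        key=key, type=etype, start=start, end=end, surface=text[start:end],
        tool=tool, norm_ids=list(norm_ids or []),
    )


def _gene_ann(doc_id, start, end, ident, source="NCBI_gene", etype="gene"):
    return NerAnnotation(
        doc_id=doc_id, start=start, end=end, type=etype, source=source, identifier=ident
    )


# -- normalization -----------------------------------------------------------

def test_exact_span_match_assigns_identifier():
    text = "aaaaaaaaaaPTENbbbbbbbbbb"
    doc = _doc(text=text)
    doc.entities["E1"] = _ent("E1", 10, 14, text)
    out = normalize_entities(doc, [_gene_ann("d1", 10, 14, "5728")])
    assert out.entities["E1"].norm_ids == [("NCBI_gene", "5728")]


def test_max_overlap_tie_breaks_to_earliest_start():
    doc = _doc()
    doc.entities["E1"] = _ent("E1", 10, 19, doc.text)
    anns = [
        _gene_ann("d1", 15, 19, "2"),  # overlap 4
        _gene_ann("d1", 10, 14, "1"),  # overlap 4, earlier start -> wins
    ]
    out = normalize_entities(doc, anns)
    assert out.entities["E1"].norm_ids == [("NCBI_gene", "1")]


def test_entity_without_overlap_is_kept_without_id():
    doc = _doc()
    doc.entities["E1"] = _ent("E1", 0, 4, doc.text)
    out = normalize_entities(doc, [_gene_ann("d1", 20, 24, "9")])
    assert out.entities["E1"].norm_ids == []


def test_annotations_for_other_document_rejected():
    doc = _doc()
    with pytest.raises(ValueError, match="d2"):
        normalize_entities(doc, [_gene_ann("d2", 0, 4, "1")])


def test_normalization_is_annotation_order_invariant():
    rng = random.Random(0)
    doc = _doc()
    doc.entities["E1"] = _ent("E1", 5, 15, doc.text)
    doc.entities["E2"] = _ent("E2", 20, 30, doc.text, etype="disease")
    anns = [
        _gene_ann("d1", 5, 10, "a"),
        _gene_ann("d1", 8, 15, "b"),
        _gene_ann("d1", 18, 25, "m1", source="MESH", etype="disease"),
        _gene_ann("d1", 22, 30, "m2", source="MESH", etype="disease"),
    ]
    baseline = normalize_entities(doc, anns)
    for _ in range(5):
        shuffled = anns[:]
        rng.shuffle(shuffled)
        assert normalize_entities(doc, shuffled) == baseline


def test_type_incompatible_annotation_ignored():
    doc = _doc()
    doc.entities["E1"] = _ent("E1", 0, 4, doc.text, etype="disease")
    out = normalize_entities(doc, [_gene_ann("d1", 0, 4, "5728")])  # gene ann
    assert out.entities["E1"].norm_ids == []


def test_gene_like_types_share_normalization_pool():
    doc = _doc()
    doc.entities["E1"] = _ent("E1", 0, 4, doc.text, etype="mirna")
    out = normalize_entities(doc, [_gene_ann("d1", 0, 4, "406991")])
    assert out.entities["E1"].norm_ids == [("NCBI_gene", "406991")]


# -- ID mapping --------------------------------------------------------------

def test_id_mapping_appends_target_identifier():
    doc = _doc()
    doc.entities["E1"] = _ent("E1", 0, 4, doc.text, norm_ids=[("NCBI_gene", "111")])
    table = IdMappingTable([("111", "P11111")])
    out = apply_id_mapping(doc, table, "NCBI_gene", "UniProt")
    assert ("UniProt", "P11111") in out.entities["E1"].norm_ids


def test_id_absent_from_table_leaves_entity_unchanged(caplog):
    doc = _doc()
    doc.entities["E1"] = _ent("E1", 0, 4, doc.text, norm_ids=[("NCBI_gene", "999")])
    with caplog.at_level("INFO", logger="annalign.integrate"):
        out = apply_id_mapping(doc, IdMappingTable([("111", "P1")]), "NCBI_gene", "UniProt")
    assert out.entities["E1"].norm_ids == [("NCBI_gene", "999")]
    assert any("no UniProt mapping" in r.message for r in caplog.records)


def test_duplicate_mapping_rows_first_wins():
    doc = _doc()
    doc.entities["E1"] = _ent("E1", 0, 4, doc.text, norm_ids=[("NCBI_gene", "111")])
    table = IdMappingTable([("111", "P1"), ("111", "P2")])
    out = apply_id_mapping(doc, table, "NCBI_gene", "UniProt")
    assert ("UniProt", "P1") in out.entities["E1"].norm_ids
    assert ("UniProt", "P2") not in out.entities["E1"].norm_ids


def test_mapping_table_from_tsv_preserves_order():
    table = IdMappingTable.from_tsv("# header\n111\tP1\n111\tP2\n222\tQ2\n")
    assert table.rows == [("111", "P1"), ("111", "P2"), ("222", "Q2")]
    assert table.first_match("111") == "P1"


# -- PubTator parsing --------------------------------------------------------

def test_parse_pubtator_fields_and_default_sources():
    anns = parse_pubtator("123\t0\t4\tPTEN\tGene\t5728\n123\t10\t16\ttumour\tDisease\tMESH:D009369\n")
    assert anns[0] == NerAnnotation("123", 0, 4, "gene", "NCBI_gene", "5728")
    assert anns[1].source == "MESH" and anns[1].identifier == "D009369"


def test_parse_pubtator_rejects_short_lines():
    with pytest.raises(ValueError, match="line 1"):
        parse_pubtator("123\t0\t4\tPTEN\tGene\n")


# -- merging -----------------------------------------------------------------

def _tool_doc(tool: str, text="AKT1 binds PTEN.", rel_type="ppi"):
    doc = Document(doc_id="d1", text=text)
    doc.entities["E1"] = _ent("E1", 0, 4, text, etype="protein", tool=tool)
    doc.entities["E2"] = _ent("E2", 11, 15, text, etype="protein", tool=tool)
    doc.relations["R1"] = Relation(
        key="R1", type=rel_type, tool=tool, arguments={"a": "E1", "b": "E2"}
    )
    return doc


def test_merge_single_input_namespaces_keys():
    merged = merge_documents([_tool_doc("alpha")])
    assert set(merged.entities) == {"alpha.E1", "alpha.E2"}
    assert merged.relations["alpha.R1"].arguments == {"a": "alpha.E1", "b": "alpha.E2"}


def test_merge_disjoint_annotations_union():
    d1 = _tool_doc("alpha")
    d2 = Document(doc_id="d1", text=d1.text)
    d2.entities["E1"] = _ent("E1", 5, 10, d1.text, etype="trigger", tool="beta")
    merged = merge_documents([d1, d2])
    assert len(merged.entities) == 3
    assert set(merged.entities) == {"alpha.E1", "alpha.E2", "beta.E1"}


def test_merge_collapses_exact_duplicates_with_provenance():
    merged = merge_documents([_tool_doc("alpha"), _tool_doc("beta")])
    assert len(merged.entities) == 2
    assert merged.entities["alpha.E1"].tool == "alpha,beta"
    assert len(merged.relations) == 1
    assert merged.relations["alpha.R1"].tool == "alpha,beta"


def test_merge_requires_identical_text():
    d1 = _tool_doc("alpha")
    d2 = _tool_doc("beta", text="AKT1 binds PTEN .")
    with pytest.raises(ValueError, match="realign"):
        merge_documents([d1, d2])


def test_merge_is_idempotent():
    merged = merge_documents([_tool_doc("alpha"), _tool_doc("beta", rel_type="binding")])
    assert merge_documents([merged]) == merged


# -- network -----------------------------------------------------------------

def _rel_doc(doc_id, ids=(("NCBI_gene", "1"), ("NCBI_gene", "2")), surfaces=("A", "B")):
    text = f"{surfaces[0]} targets {surfaces[1]}."
    doc = Document(doc_id=doc_id, text=text)
    e1 = len(surfaces[0])
    doc.entities["E1"] = _ent("E1", 0, e1, text, norm_ids=[ids[0]] if ids[0] else [])
    s2 = e1 + len(" targets ")
    doc.entities["E2"] = _ent(
        "E2", s2, s2 + len(surfaces[1]), text, norm_ids=[ids[1]] if ids[1] else []
    )
    doc.relations["R1"] = Relation(
        key="R1", type="mirna_target", tool="t", arguments={"mirna": "E1", "target": "E2"}
    )
    return doc


def test_same_relation_in_two_documents_gives_one_edge_weight_two():
    net = build_network([_rel_doc("d1"), _rel_doc("d2")])
    assert len(net.edges) == 1
    (edge,) = net.edges.values()
    assert edge.weight == 2
    assert {e[0] for e in edge.evidence} == {"d1", "d2"}


def test_entities_with_same_id_merge_to_single_node():
    d1 = _rel_doc("d1", surfaces=("p53", "B"))
    d2 = _rel_doc("d2", surfaces=("TP53", "B"))
    net = build_network([d1, d2])
    assert "NCBI_gene:1" in net.nodes
    assert len([n for n in net.nodes if n.startswith("NCBI_gene:1")]) == 1


def test_unnormalized_entities_merge_by_mention_only():
    d1 = _rel_doc("d1", ids=(None, ("NCBI_gene", "2")), surfaces=("p53", "B"))
    d2 = _rel_doc("d2", ids=(None, ("NCBI_gene", "2")), surfaces=("TP53", "B"))
    net = build_network([d1, d2])
    assert "mention:p53" in net.nodes and "mention:TP53" in net.nodes


def test_uniprot_id_preferred_over_ncbi_for_merge_key():
    doc = _rel_doc("d1")
    doc.entities["E1"].norm_ids.append(("UniProt", "P04637"))
    net = build_network([doc])
    assert "UniProt:P04637" in net.nodes


def test_edge_weight_conservation():
    docs = [_rel_doc(f"d{i}") for i in range(7)]
    net = build_network(docs)
    n_evidence = len({(d.doc_id, r.tool, k) for d in docs for k, r in d.relations.items()})
    assert net.total_weight() == n_evidence


def test_network_invariant_to_document_order():
    docs = [_rel_doc("d1"), _rel_doc("d2", surfaces=("C", "D"))]
    a = build_network(docs).to_jsonable()
    b = build_network(list(reversed(docs))).to_jsonable()
    assert a == b


def test_self_loop_when_all_arguments_merge():
    doc = _rel_doc("d1", ids=(("NCBI_gene", "1"), ("NCBI_gene", "1")))
    net = build_network([doc])
    ((u, v, _),) = net.edges.keys()
    assert u == v
    assert net.total_weight() == 1


# -- coverage statistics -----------------------------------------------------

def test_medline_coverage_percentages():
    table = corpus_stats_from_counts([236683, 27998, 393, 1])
    assert table.total == 265075
    assert table.percentages() == [
        Decimal("89.29"), Decimal("10.56"), Decimal("0.15"), Decimal("0.00")
    ]


def test_pmc_coverage_percentages():
    table = corpus_stats_from_counts([94076, 31499, 1425, 0])
    assert table.total == 127000
    assert table.percentages() == [
        Decimal("74.08"), Decimal("24.80"), Decimal("1.12"), Decimal("0.00")
    ]


def test_single_document_single_tool_is_100_percent():
    doc = _rel_doc("d1")
    table = corpus_stats([doc])
    assert table.percentages() == [Decimal("100.00")] and table.total == 1


def test_corpus_stats_counts_distinct_tools_per_document():
    doc = _rel_doc("d1")
    doc.relations["R2"] = Relation(
        key="R2", type="ppi", tool="othertool", arguments={"a": "E1", "b": "E2"}
    )
    table = corpus_stats([doc, _rel_doc("d2")])
    assert table.counts() == [1, 1]  # one 1-tool doc, one 2-tool doc


def test_corpus_stats_empty_collection_errors():
    with pytest.raises(ValueError):
        corpus_stats([])


def test_percentages_sum_to_100_within_rounding():
    table = corpus_stats_from_counts([3, 3, 1])
    assert abs(sum(table.percentages()) - Decimal("100")) <= Decimal("0.02")
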