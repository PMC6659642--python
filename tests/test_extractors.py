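"""The five extraction components and record assembly."""

import pytest

from gwascurate import parse_document
from gwascurate.docmodel import DocumentModel
from gwascurate.extractors import (
    AcronymMap,
    assemble,
    extract_document,
    extract_precise_phenotypes,
    extract_pvalue_relations,
    extract_simple_phenotypes,
    records_to_frame,
    resolve_acronyms,
)


def _empty_doc():
    return DocumentModel("p1", [], [], [], [])


class TestSimplePhenotypes:
    def test_single_dictionary_term_in_title(self, dictionary):
        doc = parse_document(
            b"<article><article-title>A study of platelet aggregation</article-title></article>"
        )
        assert extract_simple_phenotypes(doc, dictionary) == ["platelet aggregation"]

    def test_seven_loci_title(self, dictionary):
        doc = parse_document(
            b"<article><article-title>Genome-wide meta-analysis identifies seven loci "
            b"associated with platelet aggregation in response to agonists"
            b"</article-title></article>"
        )
        assert "platelet aggregation" in extract_simple_phenotypes(doc, dictionary)

    def test_no_candidates_gives_empty(self, dictionary):
        doc = parse_document(
            b"<article><article-title>A study of nothing in particular</article-title></article>"
        )
        assert extract_simple_phenotypes(doc, dictionary) == []

    def test_at_most_three_distinct_phenotypes(self, dictionary):
        doc = parse_document(
            b"<article><article-title>Variants for body mass index, platelet count, "
            b"fasting glucose and bone mineral density</article-title></article>"
        )
        out = extract_simple_phenotypes(doc, dictionary)
        assert 1 <= len(out) <= 3
        assert len(out) == len(set(out))


class TestPrecisePhenotypes:
    def test_trait_cell_joined_to_row_rsid(self, worked_example_doc):
        pairs = extract_precise_phenotypes(worked_example_doc)
        assert ("rs17661538", "Clozapine—Triglycerides") in pairs
        assert ("rs13130255", "funcPS") in pairs

    def test_numeric_cell_rejected(self):
        xml = (b"<article><article-title>t</article-title><table>"
               b"<thead><tr><th>SNP</th><th>Trait</th><th>P</th></tr></thead><tbody>"
               b"<tr><td>rs111111</td><td>platelet count</td><td>1.0E\xe2\x88\x926</td></tr>"
               b"<tr><td>rs222222</td><td>1.23</td><td>2.0E\xe2\x88\x926</td></tr>"
               b"</tbody></table></article>")
        pairs = extract_precise_phenotypes(parse_document(xml))
        assert ("rs111111", "platelet count") in pairs
        assert all(rsid != "rs222222" for rsid, _ in pairs)

    def test_rsid_only_table_yields_nothing(self):
        xml = (b"<article><article-title>t</article-title><table>"
               b"<thead><tr><th>SNP</th></tr></thead>"
               b"<tbody><tr><td>rs111111</td></tr></tbody></table></article>")
        assert extract_precise_phenotypes(parse_document(xml)) == []


class TestAcronymResolution:
    def test_text_definition_resolves(self, dictionary):
        doc = parse_document(
            b"<article><article-title>t</article-title>"
            b"<body><p>We measured body mass index (BMI) in all cohorts. "
            b"Higher BMI was associated with risk.</p></body></article>"
        )
        amap = resolve_acronyms(doc, dictionary=dictionary)
        assert amap.entries.get("BMI") == "body mass index"
        assert amap.expand("BMI") == "body mass index"

    def test_undefined_acronym_kept_verbatim(self, dictionary):
        doc = parse_document(
            b"<article><article-title>t</article-title>"
            b"<body><p>No definitions appear here.</p></body></article>"
        )
        amap = resolve_acronyms(doc, dictionary=dictionary)
        assert amap.expand("CYS5") == "CYS5"

    def test_replacement_is_whole_token_and_case_sensitive(self):
        amap = AcronymMap("d", {"BMI": "body mass index"})
        assert amap.expand("log BMI levels") == "log body mass index levels"
        assert amap.expand("SUBMIT") == "SUBMIT"  # not a whole token
        assert amap.expand("bmi") == "bmi"  # acronym side is case-sensitive

    def test_conflicting_definitions_higher_posterior_wins(self, dictionary):
        # table definition (all 4 cues fire) beats a weak text pairing
        doc = parse_document(
            b"<article><article-title>t</article-title>"
            b"<body><p>Some unrelated words precede (BMI) here.</p>"
            b"<table><thead><tr><th>Abbreviation</th><th>Description</th></tr></thead>"
            b"<tbody><tr><td>BMI</td><td>body mass index</td></tr></tbody></table>"
            b"</body></article>"
        )
        amap = resolve_acronyms(doc, dictionary=dictionary)
        assert amap.entries["BMI"] == "body mass index"


class TestPvalueRelations:
    def test_worked_example_rows_reported(self, worked_example_doc):
        rels = extract_pvalue_relations(worked_example_doc)
        triples = {(rsid, pv) for rsid, pv, _prov in rels}
        assert ("rs12566888", 5.0e-19) in triples
        assert ("rs17661538", 1.0e-6) in triples
        assert ("rs13130255", 3.0e-6) in triples

    def test_two_pvalues_in_row_give_two_tuples(self):
        xml = (b"<article><article-title>t</article-title><table>"
               b"<thead><tr><th>SNP</th><th>P disc</th><th>P repl</th></tr></thead>"
               b"<tbody><tr><td>rs111111</td><td>1.0E\xe2\x88\x926</td>"
               b"<td>0.003</td></tr></tbody></table></article>")
        rels = extract_pvalue_relations(parse_document(xml))
        assert sorted(pv for _r, pv, _p in rels) == [1.0e-6, 0.003][::-1] or len(rels) == 2


class TestAssemble:
    def test_min_pvalue_and_significance(self):
        doc = _empty_doc()
        records = assemble(
            doc,
            simple=["platelet count"],
            precise=[("rs111111", "PC")],
            acronyms=AcronymMap("p1", {"PC": "platelet count"}),
            pvalue_relations=[
                ("rs111111", 1.0e-6, ("T0", 1)),
                ("rs111111", 0.03, ("T0", 2)),
            ],
        )
        assert len(records) == 1
        rec = records[0]
        assert rec.p_value == 1.0e-6
        assert rec.significant is True
        assert rec.resolved_phenotype == "platelet count"
        assert set(rec.provenance) == {("T0", 1), ("T0", 2)}

    def test_boundary_pvalue_not_significant(self):
        records = assemble(
            _empty_doc(), [], [], AcronymMap("p1"),
            [("rs111111", 1.0e-5, ("T0", 1))],
        )
        assert records[0].significant is False

    def test_rsid_without_precise_phenotype_still_reported(self):
        records = assemble(
            _empty_doc(), ["platelet aggregation"], [], AcronymMap("p1"),
            [("rs12566888", 5.0e-19, ("T0", 1))],
        )
        assert len(records) == 1
        assert records[0].precise_phenotype is None
        assert records[0].simple_phenotypes == ("platelet aggregation",)

    def test_assembly_order_independent_and_idempotent(self):
        pv = [("rs111111", 1e-6, ("T0", 1)), ("rs222222", 1e-7, ("T0", 2))]
        precise = [("rs111111", "a"), ("rs222222", "b")]
        a = assemble(_empty_doc(), [], precise, AcronymMap("p1"), pv)
        b = assemble(_empty_doc(), [], precise[::-1], AcronymMap("p1"), pv[::-1])
        c = assemble(_empty_doc(), [], precise, AcronymMap("p1"), pv + pv)
        assert a == b == c

    def test_every_pvalue_backed_by_provenance(self, clean_docs, dictionary):
        docs, _ = clean_docs
        for doc in docs:
            pv_by_prov = {}
            for rsid, pv, prov in extract_pvalue_relations(doc):
                pv_by_prov.setdefault(prov, set()).add(pv)
            for rec in extract_document(doc, dictionary):
                assert any(
                    rec.p_value in pv_by_prov.get(prov, set())
                    for prov in rec.provenance
                )


def test_records_frame_schema(clean_docs, dictionary):
    docs, _ = clean_docs
    frame = records_to_frame(extract_document(docs[0], dictionary))
    assert list(frame.columns) == [
        "pmid", "rsid", "simple_phenotypes", "precise_phenotype",
        "resolved_phenotype", "p_value", "significant", "table_id", "row_index",
    ]
    assert len(frame) > 0
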