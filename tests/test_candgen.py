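"""Candidate generation: rsids, p-value dialects, dictionary scan, relations."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwascurate import candgen, parse_document
from gwascurate.candgen import OntologyDictionary, normalize_pvalue
from gwascurate.docmodel import Sentence, tokenize_and_tag
from gwascurate.synthcorpus import render_pvalue


def _doc(body: str = "", cell_rows: list[list[str]] | None = None, header=None):
    header = header or ["SNP", "Trait", "P value"]
    rows = ""
    for r in cell_rows or []:
        rows += "<tr>" + "".join(f"<td>{c}</td>" for c in r) + "</tr>"
    head = "<tr>" + "".join(f"<th>{h}</th>" for h in header) + "</tr>"
    xml = (
        "<article><article-title>t</article-title>"
        f"<body><p>{body}</p>"
        f"<table><thead>{head}</thead><tbody>{rows}</tbody></table></body></article>"
    )
    return parse_document(xml.encode())


class TestRsids:
    def test_single_cell_rsid(self):
        doc = _doc(cell_rows=[["rs17661538", "x", "y"]])
        assert [m.text for m in candgen.find_rsids(doc)] == ["rs17661538"]

    def test_pattern_excludes_short_and_words(self):
        doc = _doc(body="rs0 and versus and rs12 are not variants")
        assert candgen.find_rsids(doc) == []

    def test_two_rsids_in_one_sentence(self):
        doc = _doc(body="We found rs12566888 and rs13130255.")
        assert [m.text for m in candgen.find_rsids(doc)] == ["rs12566888", "rs13130255"]

    def test_offsets_identify_container_substring(self):
        doc = _doc(body="Variant rs12566888 was significant.")
        (m,) = candgen.find_rsids(doc)
        sent = doc.body[0]
        assert sent.text[m.start:m.end] == m.text


class TestPvalues:
    @pytest.mark.parametrize(
        "text,value",
        [
            ("1.00E−06", 1.0e-6),
            ("5.00E−19", 5.0e-19),
            ("3.00E−06", 3.0e-6),
            ("0.5", 0.5),
            ("1", 1.0),
            ("3.2 × 10−7", 3.2e-7),
            ("2.5×10−3", 0.0025),
            ("P = 0.03", 0.03),
            ("p < 5.0E-8", 5.0e-8),
        ],
    )
    def test_normalize_pvalue_dialects(self, text, value):
        assert normalize_pvalue(text) == pytest.approx(value, rel=1e-12)

    def test_normalize_rejects_garbage(self):
        with pytest.raises(ValueError):
            normalize_pvalue("<2e")

    def test_find_pvalues_parses_values(self):
        doc = _doc(cell_rows=[["rs111111", "t", "1.00E−06"], ["rs222222", "t", "0.5"]])
        values = sorted(m.value for m in candgen.find_pvalues(doc))
        assert values == [1.0e-6, 0.5]

    def test_plain_decimal_outside_unit_interval_not_candidate(self):
        doc = _doc(body="We recruited 1.5 million samples in 2010.")
        assert candgen.find_pvalues(doc) == []

    @settings(max_examples=100, derandomize=True)
    @given(
        mant=st.integers(100, 999),
        expo=st.integers(-19, -2),
        dialect=st.sampled_from(["enotation", "typeset", "plain"]),
    )
    def test_normalize_inverts_renderer(self, mant, expo, dialect):
        """normalize_pvalue ∘ render is the identity on all three dialects."""
        text, value = render_pvalue(mant / 100.0, expo, dialect)
        assert normalize_pvalue(text) == value


class TestDictionaryScan:
    def _sents(self, text):
        return [Sentence("s0", "title", text, tokenize_and_tag(text))]

    def test_simple_term_match(self, dictionary):
        ms = candgen.find_phenotype_candidates(
            self._sents("Seven loci associated with platelet aggregation in response to agonists"),
            dictionary,
        )
        assert [m.text.lower() for m in ms] == ["platelet aggregation"]
        assert ms[0].dict_entry == "platelet aggregation"

    def test_no_partial_surface_match(self, dictionary):
        # "bipolar patients" does not contain the term "bipolar disorder"
        ms = candgen.find_phenotype_candidates(
            self._sents("a genome-wide study in bipolar patients"), dictionary
        )
        assert ms == []

    def test_longest_match_suppresses_nested_term(self, dictionary):
        ms = candgen.find_phenotype_candidates(
            self._sents("elevated systolic blood pressure in adults"), dictionary
        )
        assert [m.text for m in ms] == ["systolic blood pressure"]

    def test_empty_dictionary_rejected(self):
        with pytest.raises(ValueError):
            OntologyDictionary({})


class TestRelations:
    def test_row_with_one_rsid_pairs_every_pvalue(self):
        doc = _doc(cell_rows=[["rs111111", "0.2", "1.0E−6"]])
        rels = candgen.generate_rsid_pvalue_relations(doc)
        assert len(rels) == 2
        assert {r.right.value for r in rels} == {0.2, 1.0e-6}

    def test_row_with_two_rsids_yields_nothing(self):
        doc = _doc(cell_rows=[["rs111111", "rs222222", "1.0E−6"]])
        assert candgen.generate_rsid_pvalue_relations(doc) == []

    def test_table_without_pvalues_yields_nothing(self):
        doc = _doc(cell_rows=[["rs111111", "trait name", "NA"]])
        assert candgen.generate_rsid_pvalue_relations(doc) == []

    def test_trait_header_generates_phenotype_relation(self):
        doc = _doc(cell_rows=[["rs111111", "Clozapine—Triglycerides", "1.00E−06"]])
        rels = candgen.generate_phenotype_pvalue_relations(doc)
        assert len(rels) == 1
        assert rels[0].left.text == "Clozapine—Triglycerides"
        assert rels[0].right.value == 1.0e-6

    def test_gene_header_is_not_a_phenotype_column(self):
        doc = _doc(header=["SNP", "Gene", "P value"],
                   cell_rows=[["rs111111", "ABCB1", "1.00E−06"]])
        assert candgen.generate_phenotype_pvalue_relations(doc) == []

    def test_header_keyword_matches_by_substring(self):
        doc = _doc(header=["SNP", "Outcome (primary)", "P value"],
                   cell_rows=[["rs111111", "stroke events", "1.00E−06"]])
        rels = candgen.generate_phenotype_pvalue_relations(doc)
        assert len(rels) == 1


class TestAcronyms:
    def test_text_pattern_pairs_expansion_and_acronym(self):
        doc = _doc(body="We measured body mass index (BMI) at baseline.")
        pairs = {(r.left.text, r.right.text) for r in candgen.generate_acronym_candidates(doc)}
        assert ("BMI", "body mass index") in pairs

    def test_table_with_abbreviation_description_headers(self):
        doc = _doc(header=["Abbreviation", "Description"],
                   cell_rows=[["funcPS", "functional protein S"]])
        pairs = {(r.left.text, r.right.text) for r in candgen.generate_acronym_candidates(doc)}
        assert pairs == {("funcPS", "functional protein S")}

    def test_transposed_definition_table(self):
        xml = (b"<article><article-title>t</article-title><table><tbody>"
               b"<tr><td>Abbreviation</td><td>BMI</td></tr>"
               b"<tr><td>Description</td><td>body mass index</td></tr>"
               b"</tbody></table></article>")
        doc = parse_document(xml)
        pairs = {(r.left.text, r.right.text) for r in candgen.generate_acronym_candidates(doc)}
        assert ("BMI", "body mass index") in pairs

    def test_year_in_parentheses_rejected(self):
        doc = _doc(body="As reported by Smith (2019) and colleagues.")
        assert candgen.generate_acronym_candidates(doc) == []


def test_planted_mentions_all_recovered(clean_docs, dictionary):
    """Candidate stage has recall 1.0 by construction on synthetic papers."""
    docs, gt = clean_docs
    for doc, truth in zip(docs, gt.papers):
        rsids = {m.text for m in candgen.find_rsids(doc)}
        pvals = {m.value for m in candgen.find_pvalues(doc)}
        phenos = {
            m.dict_entry
            for m in candgen.find_phenotype_candidates(
                [*doc.title, *doc.abstract], dictionary, doc.doc_id
            )
        }
        acro_pairs = {
            (r.left.text, r.right.text)
            for r in candgen.generate_acronym_candidates(doc)
        }
        for rsid, _printed, _resolved, pval, _t, _row in truth.associations:
            assert rsid in rsids
            assert pval in pvals
        for pheno in truth.simple_phenotypes:
            assert pheno in phenos
        for acro, expansion in truth.acronym_map.items():
            assert (acro, expansion) in acro_pairs
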