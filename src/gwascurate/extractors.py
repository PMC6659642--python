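"""The five extraction components and database assembly.

1. simple phenotypes — dictionary mentions in title/abstract, scored by the
   label model; the top ≤3 above threshold (or the single best) describe
   the whole study.
2. precise phenotypes — table cells under phenotype/trait/outcome headers,
   scored and joined to the unique rsid of their row.
3. acronym resolution — acronym/expansion pairs from definition tables and
   running text, scored; the winning map rewrites precise phenotypes.
4. (rsid, p-value) relations — horizontally aligned table pairs with at
   most one rsid per row; these are reported without classification.
5. assembly — one association record per (rsid, phenotype), keeping the
   minimum p-value with full cell-level provenance and a significance flag
   (p < 1e-5 in at least one experiment).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import candgen, labeling, labelmodel
from .candgen import CandidateRelation, OntologyDictionary
from .docmodel import DocumentModel

__all__ = [
    "ModelConfig",
    "AssociationRecord",
    "AcronymMap",
    "simple_phenotype_candidates",
    "extract_simple_phenotypes",
    "extract_precise_phenotypes",
    "resolve_acronyms",
    "extract_pvalue_relations",
    "assemble",
    "extract_document",
    "records_to_frame",
]

SIGNIFICANCE_THRESHOLD = 1e-5


@dataclass
class ModelConfig:
    """Classifier configuration shared by the three label-model stages.

    ``params`` may hold pre-fit label-model parameters (e.g. fit once over
    a whole corpus); when absent the model is fit on the candidates at
    hand.  ``threshold`` is the posterior acceptance cutoff (strict).
    """

    threshold: float = 0.5
    params: labelmodel.LabelModelParams | None = None
    max_iter: int = 500
    tol: float = 1e-6


@dataclass(frozen=True)
class AssociationRecord:
    pmid: str
    rsid: str
    simple_phenotypes: tuple[str, ...]
    precise_phenotype: str | None
    resolved_phenotype: str | None
    p_value: float
    significant: bool
    provenance: tuple[tuple[str, int], ...]  # (table_id, row_index)


@dataclass
class AcronymMap:
    doc_id: str
    entries: dict[str, str] = field(default_factory=dict)

    def expand(self, text: str) -> str:
        """Whole-token replacement, case-sensitive on the acronym side."""
        if not self.entries:
            return text
        tokens = re.split(r"(\W+)", text)
        out = [self.entries.get(t, t) for t in tokens]
        return "".join(out)


def _score(matrix: labeling.LabelMatrix, cfg: ModelConfig) -> np.ndarray:
    params = cfg.params
    if params is None:
        params = labelmodel.fit(matrix, max_iter=cfg.max_iter, tol=cfg.tol)
    return labelmodel.posterior(params, matrix)


# ---------------------------------------------------------------------------
# component 1: simple phenotypes
# ---------------------------------------------------------------------------

def simple_phenotype_candidates(
    doc: DocumentModel, dictionary: OntologyDictionary
) -> list[dict]:
    """Dictionary mentions in title + abstract with sentence context.

    Candidates are {"mention", "sentence"} dicts so labeling functions can
    inspect the container.
    """
    sentences = [*doc.title, *doc.abstract]
    by_id = {s.sent_id: s for s in sentences}
    mentions = candgen.find_phenotype_candidates(sentences, dictionary, doc.doc_id)
    return [{"mention": m, "sentence": by_id[m.container_id]} for m in mentions]


def extract_simple_phenotypes(
    doc: DocumentModel,
    dictionary: OntologyDictionary,
    lfs: list[labeling.LabelingFunction] | None = None,
    model_cfg: ModelConfig | None = None,
) -> list[str]:
    """The ≤3 highest-scoring distinct phenotype mentions above threshold.

    If no candidate clears the threshold the single top-scoring candidate
    is returned; the result is empty only when there are no candidates at
    all.  Scores are label-model posteriors over the candidate mentions.
    """
    cfg = model_cfg or ModelConfig()
    lfs = lfs or labeling.builtin_lfs("simple_phenotype")
    cands = simple_phenotype_candidates(doc, dictionary)
    if not cands:
        return []
    matrix = labeling.apply_lfs(cands, lfs)
    scores = _score(matrix, cfg)
    # distinct by canonical name, keeping each name's best score
    best: dict[str, float] = {}
    for cand, s in zip(cands, scores):
        name = cand["mention"].dict_entry or cand["mention"].text
        if s > best.get(name, -1.0):
            best[name] = float(s)
    ranked = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
    above = [name for name, s in ranked if s > cfg.threshold]
    if above:
        return above[:3]
    return [ranked[0][0]]


# ---------------------------------------------------------------------------
# component 2: precise phenotypes
# ---------------------------------------------------------------------------

def _row_rsid(doc: DocumentModel, table_id: str, row: int) -> str | None:
    """The unique rsid of a table row, or None (0 or ≥2 rsids)."""
    table = next(t for t in doc.tables if t.table_id == table_id)
    rsids = candgen._row_mentions(doc, table, row, "rsid")
    rsids = list(dict.fromkeys(m.text for m in rsids))
    return rsids[0] if len(rsids) == 1 else None


def extract_precise_phenotypes(
    doc: DocumentModel,
    lfs: list[labeling.LabelingFunction] | None = None,
    model_cfg: ModelConfig | None = None,
) -> list[tuple[str, str]]:
    """Accepted (rsid, precise phenotype) pairs from association tables.

    Phenotype/p-value relation candidates are scored by the label model;
    accepted phenotype cells are joined to the single rsid of their row.
    Rows without exactly one rsid contribute nothing.
    """
    cfg = model_cfg or ModelConfig()
    lfs = lfs or labeling.builtin_lfs("precise_phenotype")
    rels = candgen.generate_phenotype_pvalue_relations(doc)
    if not rels:
        return []
    matrix = labeling.apply_lfs(rels, lfs)
    scores = _score(matrix, cfg)
    out: list[tuple[str, str]] = []
    seen = set()
    for rel, s in zip(rels, scores):
        if s <= cfg.threshold:
            continue
        rsid = _row_rsid(doc, rel.table_id, rel.row_index)
        if rsid is None:
            continue
        key = (rsid, rel.left.text)
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out


# ---------------------------------------------------------------------------
# component 3: acronym resolution
# ---------------------------------------------------------------------------

def resolve_acronyms(
    doc: DocumentModel,
    lfs: list[labeling.LabelingFunction] | None = None,
    model_cfg: ModelConfig | None = None,
    dictionary: OntologyDictionary | None = None,
) -> AcronymMap:
    """Document-wide acronym → expansion map from scored candidate pairs.

    Candidates come from definition tables and the ``expansion (ACRO)``
    text pattern anywhere in the paper.  When two accepted pairs claim the
    same acronym the higher-posterior pair wins (ties: lexicographically
    smaller expansion, for determinism).
    """
    cfg = model_cfg or ModelConfig()
    lfs = lfs or labeling.builtin_lfs("acronym", dictionary)
    rels = candgen.generate_acronym_candidates(doc)
    amap = AcronymMap(doc.doc_id)
    if not rels:
        return amap
    matrix = labeling.apply_lfs(rels, lfs)
    scores = _score(matrix, cfg)
    best: dict[str, tuple[float, str]] = {}
    for rel, s in zip(rels, scores):
        if s <= cfg.threshold:
            continue
        acro, expansion = rel.left.text, rel.right.text
        if acro == expansion:
            continue
        cur = best.get(acro)
        cand = (float(s), expansion)
        # higher posterior wins; ties broken by the smaller expansion string
        if cur is None or cand[0] > cur[0] or (cand[0] == cur[0] and cand[1] < cur[1]):
            best[acro] = cand
    amap.entries = {a: exp for a, (_s, exp) in best.items()}
    return amap


# ---------------------------------------------------------------------------
# component 4: rsid / p-value relations (rule-based, reported in full)
# ---------------------------------------------------------------------------

def extract_pvalue_relations(
    doc: DocumentModel,
) -> list[tuple[str, float, tuple[str, int]]]:
    """All (rsid, p-value, (table_id, row)) tuples, without classification."""
    out = []
    for rel in candgen.generate_rsid_pvalue_relations(doc):
        out.append((rel.left.text, rel.right.value, (rel.table_id, rel.row_index)))
    return out


# ---------------------------------------------------------------------------
# component 5: assembly
# ---------------------------------------------------------------------------

def assemble(
    doc: DocumentModel,
    simple: list[str],
    precise: list[tuple[str, str]],
    acronyms: AcronymMap,
    pvalue_relations: list[tuple[str, float, tuple[str, int]]],
    sig_threshold: float = SIGNIFICANCE_THRESHOLD,
) -> list[AssociationRecord]:
    """Merge component outputs into one record per (rsid, phenotype).

    Each record keeps the minimum p-value over its supporting rows,
    accumulates all provenance, and is flagged significant when any of its
    p-values is strictly below ``sig_threshold``.  rsids with p-values but
    no accepted precise phenotype are still reported (phenotype absent).
    The merge is idempotent and independent of input order.
    """
    precise_by_rsid: dict[str, list[str]] = {}
    for rsid, pheno in sorted(set(precise)):
        precise_by_rsid.setdefault(rsid, []).append(pheno)

    # group p-value evidence per (rsid, precise-phenotype-or-None)
    groups: dict[tuple[str, str | None], list[tuple[float, tuple[str, int]]]] = {}
    for rsid, pval, prov in sorted(set(pvalue_relations), key=repr):
        phenos = precise_by_rsid.get(rsid) or [None]
        for pheno in phenos:
            groups.setdefault((rsid, pheno), []).append((pval, prov))

    records = []
    for (rsid, pheno), evidence in sorted(groups.items(), key=repr):
        pvals = [p for p, _ in evidence]
        provs = tuple(dict.fromkeys(prov for _, prov in sorted(evidence)))
        resolved = acronyms.expand(pheno) if pheno is not None else None
        if resolved == pheno:
            resolved = pheno  # unchanged: keep verbatim
        records.append(
            AssociationRecord(
                pmid=doc.doc_id,
                rsid=rsid,
                simple_phenotypes=tuple(simple),
                precise_phenotype=pheno,
                resolved_phenotype=resolved,
                p_value=min(pvals),
                significant=any(p < sig_threshold for p in pvals),
                provenance=provs,
            )
        )
    return records


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def extract_document(
    doc: DocumentModel,
    dictionary: OntologyDictionary,
    model_cfg: ModelConfig | None = None,
    sig_threshold: float = SIGNIFICANCE_THRESHOLD,
) -> list[AssociationRecord]:
    """Run all five components on one parsed document."""
    cfg = model_cfg or ModelConfig()
    simple = extract_simple_phenotypes(doc, dictionary, model_cfg=cfg)
    precise = extract_precise_phenotypes(doc, model_cfg=cfg)
    acronyms = resolve_acronyms(doc, model_cfg=cfg, dictionary=dictionary)
    pv = extract_pvalue_relations(doc)
    return assemble(doc, simple, precise, acronyms, pv, sig_threshold)


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    """Flatten records to the output CSV schema."""
    rows = []
    for r in records:
        for table_id, row_index in r.provenance or ((None, None),):
            rows.append(
                {
                    "pmid": r.pmid,
                    "rsid": r.rsid,
                    "simple_phenotypes": "|".join(r.simple_phenotypes),
                    "precise_phenotype": r.precise_phenotype or "",
                    "resolved_phenotype": r.resolved_phenotype or "",
                    "p_value": r.p_value,
                    "significant": r.significant,
                    "table_id": table_id,
                    "row_index": row_index,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "pmid", "rsid", "simple_phenotypes", "precise_phenotype",
            "resolved_phenotype", "p_value", "significant", "table_id",
            "row_index",
        ],
    )
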