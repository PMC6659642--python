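"""Synthetic JATS-like papers with known ground truth.

Emulates the structure the extractor consumes: a title and abstract
mentioning dictionary phenotypes, association tables with an rsid column
and a p-value column rendered in one of three typographic dialects
(E-notation, typeset ×10⁻ᵏ scientific with Unicode minus, plain decimal),
an optional precise-phenotype ("Trait") column holding acronyms, an
optional acronym-definition table (column- or row/transposed-oriented),
and distractor rows modeled on real failure modes: multiple rsids in one
row, p-values attached to haplotype identifiers, and variants reported
only in running text.

Every generated paper ships with a ground-truth sidecar (planted triples,
acronym map, table shapes) so recall/precision of any pipeline stage can
be measured exactly.  All output is deterministic given the seed.

Also provides :func:`simulate_label_matrix` — draws vote matrices from the
generative label model with known (α, β, π) for parameter-recovery tests.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .candgen import OntologyDictionary, normalize_pvalue
from .labeling import LabelMatrix

__all__ = [
    "CorpusConfig",
    "GroundTruth",
    "PaperTruth",
    "generate_corpus",
    "default_dictionary_entries",
    "simulate_label_matrix",
]

# phenotype vocabulary for the packaged mini-dictionary: (term, acronym)
_PHENOTYPES = [
    ("platelet aggregation", "PA"),
    ("body mass index", "BMI"),
    ("systolic blood pressure", "SBP"),
    ("diastolic blood pressure", "DBP"),
    ("type 2 diabetes", "T2D"),
    ("coronary artery disease", "CAD"),
    ("low density lipoprotein cholesterol", "LDLC"),
    ("high density lipoprotein cholesterol", "HDLC"),
    ("rheumatoid arthritis", "RA"),
    ("bipolar disorder", "BD"),
    ("crohn disease", "CD"),
    ("fasting glucose", "FG"),
    ("triglyceride levels", "TL"),
    ("bone mineral density", "BMD"),
    ("smoking behaviors", "SB"),
    ("platelet count", "PC"),
    ("waist hip ratio", "WHR"),
    ("macular degeneration", "MD"),
    ("prostate cancer", "PCA"),
    ("celiac disease", "CED"),
]
_SOURCES = ("EFO", "SNOMED", "MeSH")


def default_dictionary_entries() -> dict[str, tuple[str, str]]:
    """Entries for the packaged mini phenotype dictionary."""
    return {
        term: (term, _SOURCES[i % 3]) for i, (term, _a) in enumerate(_PHENOTYPES)
    }


@dataclass
class CorpusConfig:
    n_papers: int = 10
    n_dictionary_phenotypes: int = len(_PHENOTYPES)
    rows_per_table: tuple[int, int] = (3, 8)
    # weights over the three p-value dialects: enotation, typeset, plain
    dialect_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    distractor_rate: float = 0.0  # fraction of extra rows that are distractors
    acronym_rate: float = 0.7  # chance the trait column uses an acronym
    transposed_acronym_table_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("distractor_rate", "acronym_rate", "transposed_acronym_table_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_dictionary_phenotypes < 1:
            raise ValueError("empty dictionary")


@dataclass
class PaperTruth:
    doc_id: str
    simple_phenotypes: list[str]
    # (rsid, precise phenotype as printed, resolved phenotype, p_value, table_id, row)
    associations: list[tuple] = field(default_factory=list)
    acronym_map: dict[str, str] = field(default_factory=dict)
    table_shapes: dict[str, tuple[int, int]] = field(default_factory=dict)
    text_only_rsids: list[str] = field(default_factory=list)
    distractor_rows: int = 0


@dataclass
class GroundTruth:
    papers: list[PaperTruth]

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "doc_id": p.doc_id,
                    "simple_phenotypes": p.simple_phenotypes,
                    "associations": [list(a) for a in p.associations],
                    "acronym_map": p.acronym_map,
                    "table_shapes": {k: list(v) for k, v in p.table_shapes.items()},
                    "text_only_rsids": p.text_only_rsids,
                    "distractor_rows": p.distractor_rows,
                }
                for p in self.papers
            ],
            indent=1,
        )


# ---------------------------------------------------------------------------
# p-value rendering in three dialects
# ---------------------------------------------------------------------------

def render_pvalue(mantissa: float, exponent: int, dialect: str) -> tuple[str, float]:
    """Render mantissa × 10^exponent in one dialect; returns (text, value).

    ``value`` is what the text parses back to, so rendered p-values
    round-trip exactly through :func:`gwascurate.candgen.normalize_pvalue`.
    """
    value = mantissa * 10.0 ** exponent
    if dialect == "enotation":
        text = f"{mantissa:.2f}E−{abs(exponent):02d}" if exponent < 0 else f"{mantissa:.2f}E{exponent:02d}"
    elif dialect == "typeset":
        sign = "−" if exponent < 0 else ""
        text = f"{mantissa:g} × 10{sign}{abs(exponent)}"
    elif dialect == "plain":
        text = f"{value:.{max(1, -exponent + 2)}f}".rstrip("0")
        if text.endswith("."):
            text += "0"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return text, normalize_pvalue(text)


def _xml_escape(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


# ---------------------------------------------------------------------------
# paper generation
# ---------------------------------------------------------------------------

_DIALECTS = ("enotation", "typeset", "plain")


def _rand_rsid(rng: random.Random, used: set[str]) -> str:
    while True:
        rsid = f"rs{rng.randint(1, 9)}{rng.randint(0, 10**6):06d}"
        if rsid not in used:
            used.add(rsid)
            return rsid


def _make_paper(cfg: CorpusConfig, rng: random.Random, idx: int):
    doc_id = f"{90000000 + idx}"
    phenos = _PHENOTYPES[: cfg.n_dictionary_phenotypes]
    main_pheno, main_acro = rng.choice(phenos)
    truth = PaperTruth(doc_id=doc_id, simple_phenotypes=[main_pheno])
    used_rsids: set[str] = set()

    title = (
        f"Genome-wide association study identifies novel loci "
        f"for {main_pheno}"
    )
    abstract = (
        f"We conducted a genome-wide association study of {main_pheno} "
        f"({main_acro}) in a large cohort. Several variants reached "
        f"genome-wide significance."
    )
    use_acronym = rng.random() < cfg.acronym_rate
    if use_acronym:
        truth.acronym_map[main_acro] = main_pheno

    # association table
    dialect = rng.choices(_DIALECTS, weights=cfg.dialect_weights, k=1)[0]
    n_true = rng.randint(*cfg.rows_per_table)
    n_distract = sum(rng.random() < cfg.distractor_rate for _ in range(n_true))
    truth.distractor_rows = n_distract

    rows: list[tuple[str, str, str]] = []  # (rsid cell, trait cell, pvalue cell)
    for _ in range(n_true):
        rsid = _rand_rsid(rng, used_rsids)
        mant = round(rng.uniform(1.0, 9.9), 2)
        expo = -rng.randint(6, 19)
        pv_text, pv_value = render_pvalue(mant, expo, dialect)
        trait_printed = main_acro if use_acronym else main_pheno
        resolved = main_pheno
        rows.append((rsid, trait_printed, pv_text))
        truth.associations.append(
            (rsid, trait_printed, resolved, pv_value, "T0", None)
        )

    distractor_kinds = ("multi_rsid", "haplotype", "malformed")
    for _ in range(n_distract):
        kind = rng.choice(distractor_kinds)
        if kind == "multi_rsid":
            # two rsids in one row: ambiguous, must be skipped downstream
            r1, r2 = _rand_rsid(rng, used_rsids), _rand_rsid(rng, used_rsids)
            pv_text, _v = render_pvalue(round(rng.uniform(1, 9.9), 2), -rng.randint(6, 12), dialect)
            rows.append((f"{r1}, {r2}", "haplotype block", pv_text))
        elif kind == "haplotype":
            # p-value attached to a haplotype, no rsid present
            pv_text, _v = render_pvalue(round(rng.uniform(1, 9.9), 2), -rng.randint(6, 12), dialect)
            rows.append((f"HAP{rng.randint(1, 9)}", "haplotype", pv_text))
        else:
            # malformed number: not parseable as any dialect
            rsid = _rand_rsid(rng, used_rsids)
            rows.append((rsid, "see text", f"<{rng.randint(2, 9)}e"))

    rng.shuffle(rows)
    # fix up row indices in truth after shuffle (header occupies row 0)
    pos = {r[0]: i + 1 for i, r in enumerate(rows)}
    truth.associations = [
        (rsid, tp, res, pv, "T0", pos[rsid])
        for (rsid, tp, res, pv, _t, _r) in truth.associations
    ]

    assoc_rows = "\n".join(
        "<tr><td>{}</td><td>{}</td><td>{}</td></tr>".format(
            _xml_escape(a), _xml_escape(b), _xml_escape(c)
        )
        for a, b, c in rows
    )
    assoc_table = (
        "<table-wrap id=\"T0\"><table>"
        "<thead><tr><th>SNP</th><th>Trait</th><th>P value</th></tr></thead>"
        f"<tbody>\n{assoc_rows}\n</tbody>"
        "</table></table-wrap>"
    )
    truth.table_shapes["T0"] = (len(rows) + 1, 3)

    # acronym-definition table (only when the trait column is abbreviated)
    acro_table = ""
    if use_acronym:
        if rng.random() < cfg.transposed_acronym_table_rate:
            acro_table = (
                "<table-wrap id=\"T1\"><table><tbody>"
                f"<tr><td>Abbreviation</td><td>{_xml_escape(main_acro)}</td></tr>"
                f"<tr><td>Description</td><td>{_xml_escape(main_pheno)}</td></tr>"
                "</tbody></table></table-wrap>"
            )
            truth.table_shapes["T1"] = (2, 2)
        else:
            acro_table = (
                "<table-wrap id=\"T1\"><table>"
                "<thead><tr><th>Abbreviation</th><th>Description</th></tr></thead>"
                f"<tbody><tr><td>{_xml_escape(main_acro)}</td>"
                f"<td>{_xml_escape(main_pheno)}</td></tr></tbody>"
                "</table></table-wrap>"
            )
            truth.table_shapes["T1"] = (2, 2)

    # body text; optionally a text-only variant (a known recall failure mode)
    body_bits = [
        f"We tested association between genetic variants and {main_pheno} "
        f"({main_acro})." if use_acronym else
        f"We tested association between genetic variants and {main_pheno}.",
        "Association results are shown in Table 1.",
    ]
    if rng.random() < cfg.distractor_rate:
        text_rsid = _rand_rsid(rng, used_rsids)
        pv_text, _v = render_pvalue(round(rng.uniform(1, 9.9), 2), -rng.randint(6, 9), "typeset")
        body_bits.append(
            f"An additional variant {text_rsid} showed suggestive evidence "
            f"(P = {pv_text}) but was not replicated."
        )
        truth.text_only_rsids.append(text_rsid)
    body = " ".join(body_bits)

    xml = f"""<article id="{doc_id}">
 <front>
  <article-meta>
   <article-id pub-id-type="pmid">{doc_id}</article-id>
   <title-group><article-title>{_xml_escape(title)}</article-title></title-group>
   <abstract><p>{_xml_escape(abstract)}</p></abstract>
  </article-meta>
 </front>
 <body>
  <p>{_xml_escape(body)}</p>
  {assoc_table}
  {acro_table}
 </body>
</article>
"""
    return xml.encode("utf-8"), truth


def generate_corpus(
    config: CorpusConfig, out_dir: str | Path | None = None
) -> tuple[dict[str, bytes], GroundTruth]:
    """Generate ``n_papers`` XML papers plus their ground-truth sidecar.

    Returns ({filename: xml bytes}, GroundTruth); when ``out_dir`` is
    given the files and ``ground_truth.json`` are also written there.
    Byte-identical output for identical configs.
    """
    rng = random.Random(config.seed)
    papers: dict[str, bytes] = {}
    truths: list[PaperTruth] = []
    for i in range(config.n_papers):
        xml, truth = _make_paper(config, rng, i)
        papers[f"{truth.doc_id}.xml"] = xml
        truths.append(truth)
    gt = GroundTruth(truths)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, data in papers.items():
            (out / name).write_bytes(data)
        (out / "ground_truth.json").write_text(gt.to_json())
    return papers, gt


def corpus_dictionary(config: CorpusConfig) -> OntologyDictionary:
    """The dictionary matching a generated corpus's phenotype vocabulary."""
    entries = dict(list(default_dictionary_entries().items())[: config.n_dictionary_phenotypes])
    return OntologyDictionary(entries)


# ---------------------------------------------------------------------------
# simulated label matrices with known parameters
# ---------------------------------------------------------------------------

def simulate_label_matrix(
    n: int,
    alphas,
    betas,
    pi: float,
    seed: int = 0,
) -> tuple[LabelMatrix, np.ndarray]:
    """Draw an n × m vote matrix from the generative model.

    y_i ~ ±1 with P(+1) = pi; LF j votes with probability β_j and, when
    voting, agrees with y_i with probability α_j.  Returns the matrix and
    the true labels (the latter are for evaluation only — the model is fit
    without them).
    """
    alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    # endpoints allowed: α=1/β=1 give perfect columns, β=0 all-abstain
    if not ((alphas >= 0) & (alphas <= 1)).all() or not ((betas >= 0) & (betas <= 1)).all():
        raise ValueError("alphas and betas must lie in [0, 1]")
    if not 0.0 < pi < 1.0:
        raise ValueError("pi must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    m = alphas.size
    y = np.where(rng.random(n) < pi, 1, -1)
    votes = np.zeros((n, m), dtype=np.int8)
    voted = rng.random((n, m)) < betas
    agree = rng.random((n, m)) < alphas
    votes[voted & agree] = np.broadcast_to(y[:, None], (n, m))[voted & agree]
    votes[voted & ~agree] = -np.broadcast_to(y[:, None], (n, m))[voted & ~agree]
    ids = [f"c{i}" for i in range(n)]
    names = [f"lf{j}" for j in range(m)]
    return LabelMatrix(votes, ids, names), y
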