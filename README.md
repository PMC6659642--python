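# gwascurate

Machine curation of the GWAS literature. `gwascurate` reads full-text
genome-wide association study publications in JATS/PMC-style XML and emits a
structured table of **(publication, variant rsid, phenotype, p-value)**
associations — the relation human curators extract by hand when building
databases such as the GWAS Catalog. It is aimed at anyone who needs
machine-readable association data from open-access GWAS papers: curators
triaging new studies, and methodologists studying weak supervision on
scientific text.

## How it works

Each paper passes through three stages:

1. **Parsing.** The XML tree becomes a hierarchical document model — title,
   abstract and body sentences (tokenized, with a per-token noun flag) and
   tables expanded into dense cell grids so that *horizontally aligned* has a
   single meaning even under `rowspan`/`colspan`.
2. **Candidate generation** (high recall). Regexes propose variant rsids
   (`rs` + ≥3 digits) and p-values in three typographic dialects
   (`1.00E−06`, `3.2 × 10−7`, plain decimals); an ontology-style dictionary
   (EFO/SNOMED/MeSH-like term list) proposes phenotype mentions by
   longest-surface match; aligned table cells and the text pattern
   `expansion (ACRO)` propose acronym definitions.
3. **Classification without labeled data** (data programming). Hand-written
   labeling functions (LFs) vote +1/−1/abstain on each candidate — e.g. *is
   the mention in the title*, *is the cell mostly a number*, *do the acronym
   letters match the expansion's word initials*. A generative Naive Bayes
   model treats the true label y ∈ {−1, +1} as latent: LF *j* votes with
   propensity β_j and, conditional on voting, agrees with y with accuracy
   α_j. The parameters (α, β, π) are fit by EM on the unlabeled vote matrix
   alone, and the posteriors P(y = +1 | votes) are used directly as
   probabilistic predictions (acceptance at posterior > 0.5).

Five extraction components share these stages: **simple phenotypes**
(study-level traits from title/abstract, top ≤3 by posterior), **precise
phenotypes** (table cells under phenotype/trait/outcome headers, joined to
the unique rsid of their row), **acronym resolution** (document-wide map
applied to precise phenotypes), **(rsid, p-value) relations** (aligned table
pairs, at most one rsid per row, reported without classification), and
**assembly** into one record per (rsid, phenotype) keeping the minimum
p-value, full cell-level provenance and a significance flag (p < 10⁻⁵).

The package also ships an **evaluation harness** (recall/precision against a
reference catalog through an exact/approximate phenotype mapping table), an
**LD novelty filter** (drop extracted variants whose dosage correlation r²
with a known variant of the same paper exceeds 0.5), and a **synthetic
corpus generator** that plants known associations in JATS-like XML so every
stage is testable offline with exact ground truth.

## Worked example

```bash
gwascurate simulate --out corpus --n-papers 3 --seed 5
gwascurate extract --input corpus \
    --dict src/gwascurate/data/phenotypes_mini.tsv --out assoc.csv
head -3 assoc.csv
```

```
wrote 3 papers + ground_truth.json to corpus
wrote 19 association rows to assoc.csv
pmid,rsid,simple_phenotypes,precise_phenotype,resolved_phenotype,p_value,significant,table_id,row_index
90000000,rs1219630,celiac disease,CED,celiac disease,7.88e-08,True,T0,5
90000000,rs1766701,celiac disease,CED,celiac disease,2.93e-10,True,T0,1
```

Each row is one extracted association: study 90000000's trait column printed
the acronym `CED`, which the acronym resolver expanded to *celiac disease*
via the paper's definition table; the p-value 7.88e-08 was parsed from the
table cell at (T0, row 5) and is below 10⁻⁵, so the record is flagged
significant. Scoring against the generator's ground truth:

```bash
gwascurate evaluate --extracted assoc.csv --reference ref.tsv --level exact
```

```
recall (exact): 1.000
recovered_exact: 19
recovered_approx: 0
wrong_phenotype: 0
missed_variant: 0
```

The library surface mirrors the CLI: `parse_document`, `extract_document`,
`normalize_pvalue`, `labelmodel.fit/posterior/predict`,
`evalharness.match/error_breakdown`, `ldnovelty.compute_r2/filter_novel`,
`synthcorpus.generate_corpus/simulate_label_matrix`.

## Limitations

Extraction is table-centric: variants whose p-values appear only in running
text are not recovered, mirroring a known failure mode of table-based
curation. The noun tagger is rule-based (closed-class list + suffixes), not
a full POS model. Effect sizes, risk alleles, cohorts and ancestry metadata
are out of scope.
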