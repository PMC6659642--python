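# Methods

## The extraction model

`gwascurate` treats literature curation as relation extraction with weak
supervision. For each target relation (simple phenotype, precise phenotype,
acronym definition) the pipeline separates *candidate generation* — a
deliberately over-inclusive enumeration by regex, dictionary scan or table
alignment — from *classification*, which decides which candidates are real.
Classification uses no hand-labeled training data: a small set of
hand-written labeling functions (LFs) votes on every candidate, and a
generative model learns from the vote matrix alone how much to trust each
LF. (rsid, p-value) pairs skip classification entirely: aligned table pairs
with a unique row rsid are accurate enough to report as-is, so that stage
stays rule-based.

### Generative label model

For candidate *i* with latent label y_i ∈ {−1, +1}, P(y = +1) = π, LF *j*
abstains with probability 1 − β_j, and conditional on voting agrees with
y_i with probability α_j (votes are conditionally independent given y —
Naive Bayes; LF correlations are not modeled). Abstention carries no class
information, so β cancels from the posterior and is estimated directly as
smoothed empirical coverage. α and π are fit by EM:

- E-step: q_i = P(y_i = +1 | votes) by Bayes' rule in log space.
- M-step: closed-form updates with add-1 pseudo-counts (a Beta(2,2)-style
  regularizer that keeps every parameter strictly inside (0,1)).
- Initialization α = 0.7, β = coverage, π = 0.5; convergence when the
  marginal log-likelihood improves by < 1e−6, cap 500 iterations. The
  add-1 smoothing makes this MAP-EM; the per-iteration log-likelihood trace
  is stored and tested non-decreasing to a 1e−9 numerical floor.
- The likelihood is invariant under (α, π) → (1 − α, 1 − π). The fit
  returns the branch with mean α ≥ 1/2, i.e. it assumes LFs are better than
  random on average. With a single LF and π = 0.5 the likelihood is flat
  along the ridge πα + (1 − π)(1 − α) = const, so α is unidentifiable
  there; tests assert only identifiable quantities in that regime and full
  recovery at m = 5.

EM with closed-form M-steps was chosen over stochastic gradient descent on
the marginal likelihood because it is deterministic given the
initialization and its monotonicity is a checkable invariant. Posteriors
are used directly as predictions; acceptance is strict (p > threshold,
default 0.5, ties rejected).

### Labeling functions and polarities

The LF registries are small and extensible. Polarities follow each cue's
obvious intent: in-title → +1, mention < 5 characters → −1, contains a
noun → ±1 (two-sided), first half of sentence → +1; cell mostly a number →
−1 / mostly alphabetic → +1 (two-sided), column header > 30 characters →
−1, rsid-like words in the cell → −1; all-caps acronym → +1, expansion in
the phenotype dictionary → +1, acronym letters = word initials → ±1
(two-sided, digits count as words so T2D ↔ "type 2 diabetes"), one string
a prefix of the other → +1. The precise-phenotype set is three LFs, all of
whose informative cues are negative; the mostly-a-number LF is made
two-sided so that a clean phenotype cell accrues positive evidence —
otherwise no candidate could ever clear a strict 0.5 threshold under a
symmetric prior. Mis-set polarity degrades gracefully because the label
model learns per-LF accuracy (an LF learned to α < 0.5 effectively flips).

Thresholds that matter: "short mention" < 5 characters, "very long header"
> 30 characters, "mostly a number" > 50% numeric characters, posterior
acceptance 0.5, significance p < 10⁻⁵ (strict) — all configurable.

### Document model conventions

Tables are expanded into dense 0-based grids: spans are clamped at table
edges, pathological span overlaps are shrunk column-first, ragged rows are
padded with empty filler cells, so every (row, col) maps to exactly one
cell. Multi-row headers are concatenated top-to-bottom with single spaces
into each body cell's `column_header_text`; a header spanning several
columns contributes its text to every column it covers, once. Sentence
splitting is punctuation + capital-letter with an abbreviation guard; the
noun flag comes from a closed-class word list plus suffix heuristics, which
is sufficient because only one LF consumes it.

### Assembly

Records merge per (rsid, resolved-or-precise phenotype): minimum p-value,
accumulated (table, row) provenance, significance = any p < 10⁻⁵ strictly.
All associations are retained with the flag rather than filtered, so users
can apply their own inclusion criterion. Acronym replacement is whole-token
and case-sensitive on the acronym side; an acronym with two accepted
definitions resolves to the higher-posterior pair (ties to the
lexicographically smaller expansion, for determinism).

## Evaluation harness

A reference association is *recovered* when an extracted record shares its
pmid and rsid and some extracted phenotype (resolved, precise or simple)
maps to the reference phenotype at the requested level. Identical strings
(case/whitespace-folded) are always exact; anything else must appear in a
user-supplied mapping table with level `exact` or `approximate` —
externalizing a judgment that is ultimately human. p-values are not
required to match for recovery (an optional relative-tolerance check
exists), because curated databases frequently print the replication or
meta-analysis p rather than the discovery p. Phenotype precision is
estimated only over catalog-confirmed variants: records whose (pmid, rsid)
occurs in the reference in any relation, so phenotype correctness is
measured independently of variant recall.

## LD novelty filter

r² is the squared Pearson correlation of allele-dosage vectors (0/1/2) —
genotype-based, needing no phasing, symmetric and invariant to allele
relabeling. Filtering is within-paper and two-pass: first drop extracted
variants with r² > 0.5 against any known variant of the same paper, then
greedily deduplicate survivors in ascending-p-value order (ties by rsid) so
a cluster of mutually linked novel variants is reported once. Variants
absent from the panel are retained and flagged rather than silently
dropped, since absence of evidence of linkage is not evidence of novelty.
Pass-2 ordering is a design choice the underlying problem does not fix; the
ascending-p rule keeps the statistically strongest representative.

## Synthetic corpus

The generator emulates the structural features the extractor depends on:
a title and abstract containing one dictionary phenotype; one association
table per paper with SNP/Trait/P-value columns, 3–8 true rows, the p-value
column rendered in one of three dialects (E-notation with Unicode minus,
typeset m × 10⁻ᵏ, plain decimal) with mantissas in [1.0, 9.9] and
exponents −6…−19; a 70% chance the trait column prints an acronym defined
in a separate two-column definition table (30% of those transposed to
row-oriented); and distractor rows drawn from observed real-world failure
modes — two rsids in one row, p-values attached to haplotype identifiers,
malformed numbers, and variants mentioned only in running text. Ground
truth is recorded at generation time and every planted p-value round-trips
exactly through the parser's normalizer, so recall and precision are exact
set comparisons, not fuzzy matches.

What the generator does **not** emulate: realistic prose (phenotypes
outside the dictionary, traits mentioned only in passing), multi-phenotype
studies, nested or transposed association-table headers, journal-specific
XML quirks, and OCR-grade noise. Passing tests therefore demonstrate the
pipeline's correctness on well-formed table-centric papers and its
robustness to the modeled distractors — not performance on arbitrary
real-world XML, where dictionary coverage and table layout variation
dominate the error budget.

## Problem sizes and numerical choices

The test suite and the acceptance script use a 50-paper corpus for
end-to-end metrics, n = 5000 × 5 LFs × 10 seeds for parameter recovery,
all 3^m vote rows for m ≤ 3 against brute-force enumeration (agreement to
1e−10), 100 random fixtures for the evaluation-harness partition property,
and a 9-variant, 300-sample block-structured panel for the LD sweep —
sizes at which every quantity is stable across seeds. Degenerate inputs
are defined throughout: empty documents parse to empty models, an
all-abstain row scores the prior, zero-variance dosage vectors raise
rather than return NaN, and an empty candidate list yields a 0 × m matrix.
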