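"""Hand-written labeling functions (LFs) and the label matrix.

An LF is a deterministic heuristic voting +1 (looks correct), -1 (looks
wrong) or 0 (abstain) on a candidate.  LFs may be noisy, overlap and
conflict; the generative label model downstream learns their accuracies
from the unlabeled vote matrix alone.

Three registered LF sets, one per classified candidate kind:

``simple_phenotype``
    votes on dictionary phenotype mentions from titles/abstracts — is the
    mention in the title; is it shorter than five characters; does it
    contain nouns; does it sit in the first half of its sentence.
``precise_phenotype``
    votes on table-cell phenotype candidates — is the cell mostly a
    number; is its column header very long; does it contain rsid-like
    words.
``acronym``
    votes on acronym/expansion pairs — is the acronym all caps; does the
    expansion match the phenotype dictionary; do the acronym letters match
    the expansion's word initials; is one string a prefix of the other.

Polarities follow the obvious intent of each cue (short mention -> -1,
in-title -> +1, ...); mis-set polarity degrades gracefully because the
label model learns per-LF accuracy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .candgen import RSID_RE, CandidateRelation, Mention, OntologyDictionary
from .docmodel import tokenize_and_tag

__all__ = ["LabelingFunction", "LabelMatrix", "apply_lfs", "builtin_lfs", "lf_summary"]

# thresholds exposed for configuration
SHORT_MENTION_CHARS = 5
VERY_LONG_HEADER_CHARS = 30
MOSTLY_NUMBER_FRACTION = 0.5


@dataclass(frozen=True)
class LabelingFunction:
    name: str
    kind: str  # simple_phenotype | precise_phenotype | acronym
    fn: Callable[[object], int]

    def __call__(self, candidate) -> int:
        vote = self.fn(candidate)
        if vote not in (-1, 0, 1):
            raise ValueError(f"LF {self.name} returned {vote!r}, not in {{-1,0,+1}}")
        return vote


@dataclass
class LabelMatrix:
    values: np.ndarray  # (n_candidates, n_lfs), entries in {-1, 0, +1}
    candidate_ids: list[str]
    lf_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise ValueError("label matrix entries must be in {-1, 0, +1}")
        if len(set(self.lf_names)) != len(self.lf_names):
            raise ValueError("LF names must be unique")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


def apply_lfs(candidates: list, lfs: list[LabelingFunction]) -> LabelMatrix:
    """Evaluate every LF on every candidate -> n x m vote matrix."""
    kinds = {lf.kind for lf in lfs}
    if len(kinds) > 1:
        raise ValueError(f"LFs target mixed kinds: {sorted(kinds)}")
    values = np.zeros((len(candidates), len(lfs)), dtype=np.int8)
    for i, cand in enumerate(candidates):
        for j, lf in enumerate(lfs):
            values[i, j] = lf(cand)
    ids = [_candidate_id(c, i) for i, c in enumerate(candidates)]
    return LabelMatrix(values, ids, [lf.name for lf in lfs])


def _candidate_id(cand, i: int) -> str:
    if isinstance(cand, Mention):
        return f"{cand.doc_id}:{cand.container_id}:{cand.start}-{cand.end}"
    if isinstance(cand, CandidateRelation):
        l, r = cand.left, cand.right
        return (
            f"{l.doc_id}:{l.container_id}:{l.start}-{l.end}"
            f"|{r.container_id}:{r.start}-{r.end}"
        )
    return str(i)


def lf_summary(matrix: LabelMatrix) -> dict[str, dict[str, float]]:
    """Per-LF coverage/overlap/conflict rates (diagnostics, logged per run)."""
    v = matrix.values
    n = max(1, matrix.n)
    voted = v != 0
    out = {}
    for j, name in enumerate(matrix.lf_names):
        others = np.delete(voted, j, axis=1).any(axis=1) if matrix.m > 1 else np.zeros(n, bool)
        overlap = (voted[:, j] & others).mean()
        conflict = 0.0
        if matrix.m > 1:
            other_vals = np.delete(v, j, axis=1)
            disagree = ((other_vals != 0) & (other_vals != v[:, [j]])).any(axis=1)
            conflict = (voted[:, j] & disagree).mean()
        out[name] = {
            "coverage": float(voted[:, j].mean()),
            "overlap": float(overlap),
            "conflict": float(conflict),
        }
    return out


# ---------------------------------------------------------------------------
# simple-phenotype LFs (mentions in title/abstract, with sentence context)
# ---------------------------------------------------------------------------
# candidates are dicts {"mention": Mention, "sentence": Sentence} so LFs can
# see the container; see extractors.simple_phenotype_candidates.


def _lf_in_title(c) -> int:
    return 1 if c["sentence"].container == "title" else 0


def _lf_short_mention(c) -> int:
    return -1 if len(c["mention"].text) < SHORT_MENTION_CHARS else 0


def _lf_contains_noun(c) -> int:
    toks = tokenize_and_tag(c["mention"].text)
    return 1 if any(t.is_noun for t in toks) else -1


def _lf_first_half(c) -> int:
    sent_len = max(1, len(c["sentence"].text))
    return 1 if c["mention"].start < sent_len / 2 else 0


# ---------------------------------------------------------------------------
# precise-phenotype LFs (phenotype_pvalue relations; left = phenotype cell)
# ---------------------------------------------------------------------------

_RSID_WORDS = ("snp", "rsid", "variant", "allele", "marker")


def _lf_mostly_number(rel: CandidateRelation) -> int:
    text = rel.left.text
    chars = [ch for ch in text if not ch.isspace()]
    if not chars:
        return -1
    frac_num = sum(ch.isdigit() or ch in ".,%-" for ch in chars) / len(chars)
    # two-sided: a mostly-alphabetic cell is positive evidence of a phenotype
    return -1 if frac_num > MOSTLY_NUMBER_FRACTION else 1


def _lf_very_long_header(rel: CandidateRelation) -> int:
    return -1 if len(rel.header_text) > VERY_LONG_HEADER_CHARS else 0


def _lf_rsid_words(rel: CandidateRelation) -> int:
    text = rel.left.text.lower()
    if RSID_RE.search(text):
        return -1
    if any(re.search(rf"\b{w}s?\b", text) for w in _RSID_WORDS):
        return -1
    return 0


# ---------------------------------------------------------------------------
# acronym LFs (acronym_expansion relations; left = acronym, right = expansion)
# ---------------------------------------------------------------------------


def _lf_all_caps(rel: CandidateRelation) -> int:
    acro = rel.left.text
    alpha = [ch for ch in acro if ch.isalpha()]
    return 1 if alpha and all(ch.isupper() for ch in alpha) else 0


def _lf_initials_match(rel: CandidateRelation) -> int:
    # digits count as words so "T2D" matches "type 2 diabetes"
    acro = re.sub(r"[^A-Za-z0-9]", "", rel.left.text).lower()
    words = re.findall(r"\w+", rel.right.text)
    initials = "".join(w[0].lower() for w in words)
    if not acro or not initials:
        return 0
    return 1 if acro == initials else -1


def _lf_prefix(rel: CandidateRelation) -> int:
    a = rel.left.text.lower().replace(" ", "")
    e = rel.right.text.lower().replace(" ", "")
    if not a or not e:
        return 0
    return 1 if e.startswith(a) or a.startswith(e) else 0


def _make_lf_in_dictionary(dictionary: OntologyDictionary | None) -> LabelingFunction:
    def fn(rel: CandidateRelation) -> int:
        if dictionary is None:
            return 0
        return 1 if rel.right.text in dictionary else 0

    return LabelingFunction("expansion_in_dictionary", "acronym", fn)


def builtin_lfs(kind: str, dictionary: OntologyDictionary | None = None) -> list[LabelingFunction]:
    """The registered LF set for one candidate kind.

    The registry is deliberately small (each classifier uses a handful of
    hand-crafted heuristics) and extensible: append further
    :class:`LabelingFunction` instances to the returned list.
    """
    if kind == "simple_phenotype":
        return [
            LabelingFunction("mention_in_title", kind, _lf_in_title),
            LabelingFunction("mention_shorter_than_5_chars", kind, _lf_short_mention),
            LabelingFunction("mention_contains_noun", kind, _lf_contains_noun),
            LabelingFunction("mention_in_first_half_of_sentence", kind, _lf_first_half),
        ]
    if kind == "precise_phenotype":
        return [
            LabelingFunction("cell_mostly_a_number", kind, _lf_mostly_number),
            LabelingFunction("column_header_very_long", kind, _lf_very_long_header),
            LabelingFunction("cell_contains_rsid_words", kind, _lf_rsid_words),
        ]
    if kind == "acronym":
        return [
            LabelingFunction("acronym_all_caps", kind, _lf_all_caps),
            _make_lf_in_dictionary(dictionary),
            LabelingFunction("acronym_matches_word_initials", kind, _lf_initials_match),
            LabelingFunction("one_is_prefix_of_other", kind, _lf_prefix),
        ]
    raise ValueError(f"unknown LF kind: {kind!r}")
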