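"""High-recall candidate generation: rsids, p-values, phenotypes, acronyms.

Candidate generation errs on the side of recall — every span that could be
an instance of a target relation is proposed; the weakly supervised
classifier downstream decides which candidates are real.

Patterns
--------
rsid        ``rs`` + >=3 digits, no leading zero, word-bounded, case-insensitive.
p-value     three typographic dialects: E-notation (``1.00E-06``), typeset
            scientific (``3.2 × 10−7``, tolerant of the Unicode minus and
            multiplication signs and of flattened superscripts), and plain
            decimals in (0, 1].
acronym     ``<expansion words> (<ACRO>)`` in running text, plus aligned
            table cells under abbreviation/description-style headers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .docmodel import Cell, DocumentModel, Table

__all__ = [
    "Mention",
    "CandidateRelation",
    "OntologyDictionary",
    "RSID_RE",
    "find_rsids",
    "find_pvalues",
    "normalize_pvalue",
    "find_phenotype_candidates",
    "generate_rsid_pvalue_relations",
    "generate_phenotype_pvalue_relations",
    "generate_acronym_candidates",
]


@dataclass(frozen=True)
class Mention:
    doc_id: str
    container_id: str  # sentence id or "<table_id>:r<row>c<col>"
    start: int
    end: int
    text: str
    role: str  # rsid | pvalue | phenotype | acronym | expansion
    value: float | None = None  # pvalue role only
    dict_entry: str | None = None  # phenotype role: canonical ontology name


@dataclass(frozen=True)
class CandidateRelation:
    kind: str  # rsid_pvalue | phenotype_pvalue | acronym_expansion
    left: Mention
    right: Mention
    table_id: str | None = None
    row_index: int | None = None
    header_text: str = ""  # phenotype_pvalue: column header governing left


class OntologyDictionary:
    """Flat phenotype term dictionary (EFO/SNOMED/MeSH-style).

    Case-insensitive exact-surface lookup; a trailing plural ``s`` is
    stripped as the only normalization.  No stemming, no fuzzy matching:
    candidates are surface matches only.
    """

    def __init__(self, entries: dict[str, tuple[str, str]]):
        if not entries:
            raise ValueError("empty dictionary")
        self._entries: dict[str, tuple[str, str]] = {}
        for term, (canonical, source) in entries.items():
            term = term.strip().lower()
            if not term:
                raise ValueError("dictionary terms must be non-empty")
            self._entries[term] = (canonical, source)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OntologyDictionary":
        """Load a 2-3 column TSV: term, canonical name[, source]."""
        entries: dict[str, tuple[str, str]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            term = parts[0]
            canonical = parts[1] if len(parts) > 1 and parts[1] else term
            source = parts[2] if len(parts) > 2 else "EFO"
            entries[term] = (canonical, source)
        return cls(entries)

    def lookup(self, term: str) -> tuple[str, str] | None:
        key = term.strip().lower()
        hit = self._entries.get(key)
        if hit is None and key.endswith("s"):
            hit = self._entries.get(key[:-1])
        return hit

    def __contains__(self, term: str) -> bool:
        return self.lookup(term) is not None

    def __len__(self) -> int:
        return len(self._entries)

    def terms(self) -> list[str]:
        return sorted(self._entries)


# ---------------------------------------------------------------------------
# rsid candidates
# ---------------------------------------------------------------------------

RSID_RE = re.compile(r"\brs[1-9][0-9]{2,}\b", re.IGNORECASE)


def _iter_containers(doc: DocumentModel):
    """Yield (container_id, text) over sentences then table cells."""
    for sent in doc.sentences():
        yield sent.sent_id, sent.text
    for table in doc.tables:
        for cell in table.cells:
            if cell.text:
                yield f"{table.table_id}:r{cell.row}c{cell.col}", cell.text


def find_rsids(doc: DocumentModel) -> list[Mention]:
    """Every maximal rsid-pattern match in sentences and table cells."""
    out = []
    for cid, text in _iter_containers(doc):
        for m in RSID_RE.finditer(text):
            out.append(
                Mention(doc.doc_id, cid, m.start(), m.end(), m.group(), "rsid")
            )
    return out


# ---------------------------------------------------------------------------
# p-value candidates: three typographic dialects
# ---------------------------------------------------------------------------

_MINUS = "[−‐–—-]"  # unicode minus, hyphens, dashes
_SP = "[ \u00a0\u2009\u202f]*"  # ascii/nbsp/thin/narrow spaces

# dialect 1: E-notation  1.00E-06
_PV_ENOT = rf"\d+(?:\.\d+)?{_SP}[eE]{_SP}{_MINUS}?{_SP}\d+"
# dialect 2: typeset scientific  3.2 × 10−7  (also x, ·, *)
_PV_TYPESET = rf"\d+(?:\.\d+)?{_SP}[×x×⋅·*]{_SP}10{_SP}(?:\^|<sup>)?{_SP}{_MINUS}?{_SP}\d+(?:</sup>)?"
# dialect 3: plain decimal in (0,1]
_PV_PLAIN = r"(?:0?\.\d+|1\.0+|1(?!\d)(?!\.\d))"

PVALUE_RE = re.compile(
    rf"(?<![\w.])(?:(?P<typeset>{_PV_TYPESET})|(?P<enot>{_PV_ENOT})|(?P<plain>{_PV_PLAIN}))(?![\w.])"
)

_ENOT_PARSE = re.compile(
    rf"^(?P<mant>\d+(?:\.\d+)?){_SP}[eE]{_SP}(?P<sign>{_MINUS})?{_SP}(?P<exp>\d+)$"
)
_TYPESET_PARSE = re.compile(
    rf"^(?P<mant>\d+(?:\.\d+)?){_SP}[×x×⋅·*]{_SP}10{_SP}(?:\^|<sup>)?{_SP}(?P<sign>{_MINUS})?{_SP}(?P<exp>\d+)(?:</sup>)?$"
)


def normalize_pvalue(text: str) -> float:
    """Parse one p-value string in any of the three dialects to a float.

    Tolerates a leading ``P =`` / ``p <`` qualifier, the Unicode minus
    (U+2212) and relatives, ``×``/``·``/``x`` multiplication signs and
    thin spaces.  Raises :class:`ValueError` on non-matching text.
    """
    s = text.strip()
    s = re.sub(rf"^[Pp]{_SP}(?:value)?{_SP}[=<>≤≥]{_SP}", "", s)
    m = _ENOT_PARSE.match(s)
    if m is None:
        m = _TYPESET_PARSE.match(s)
    if m is not None:
        mant = float(m.group("mant"))
        exp = int(m.group("exp"))
        if m.group("sign"):
            exp = -exp
        return mant * 10.0 ** exp
    try:
        return float(s)
    except ValueError:
        raise ValueError(f"not a recognized p-value dialect: {text!r}") from None


def find_pvalues(doc: DocumentModel) -> list[Mention]:
    """All dialect matches, each carrying its normalized float value.

    Plain decimals are only candidates when they lie in (0, 1]; values
    that overflow or fall outside that range are dropped.
    """
    out = []
    for cid, text in _iter_containers(doc):
        for m in PVALUE_RE.finditer(text):
            raw = m.group()
            try:
                value = normalize_pvalue(raw)
            except (ValueError, OverflowError):
                continue
            if not (0.0 < value <= 1.0):
                continue
            out.append(
                Mention(doc.doc_id, cid, m.start(), m.end(), raw, "pvalue", value=value)
            )
    return out


# ---------------------------------------------------------------------------
# phenotype candidates: dictionary longest-match scan
# ---------------------------------------------------------------------------

_WORD_RE = re.compile(r"\w+")


def find_phenotype_candidates(
    sentences, dictionary: OntologyDictionary, doc_id: str = ""
) -> list[Mention]:
    """Case-insensitive longest-match dictionary scan over sentences.

    At each word start the longest dictionary term match wins; shorter
    terms nested inside an accepted match are suppressed, and matches
    never overlap.
    """
    if len(dictionary) == 0:  # defensive; constructor already forbids
        raise ValueError("empty dictionary")
    # term word-length index for bounded lookahead
    max_words = max(len(t.split()) for t in dictionary.terms())
    out = []
    for sent in sentences:
        text = sent.text
        words = list(_WORD_RE.finditer(text))
        taken_until = -1
        i = 0
        while i < len(words):
            if words[i].start() <= taken_until:
                i += 1
                continue
            best = None
            for j in range(min(len(words), i + max_words) - 1, i - 1, -1):
                span_text = text[words[i].start():words[j].end()]
                hit = dictionary.lookup(span_text)
                if hit is not None:
                    best = (words[i].start(), words[j].end(), span_text, hit)
                    break  # longest first
            if best is not None:
                start, end, span_text, (canonical, _src) = best
                out.append(
                    Mention(
                        doc_id or getattr(sent, "doc_id", ""),
                        sent.sent_id,
                        start,
                        end,
                        span_text,
                        "phenotype",
                        dict_entry=canonical,
                    )
                )
                taken_until = end - 1
            i += 1
    return out


# ---------------------------------------------------------------------------
# relation candidates from tables
# ---------------------------------------------------------------------------

def _cell_id(table: Table, cell: Cell) -> str:
    return f"{table.table_id}:r{cell.row}c{cell.col}"


def _row_mentions(doc: DocumentModel, table: Table, row: int, role: str) -> list[Mention]:
    """Mentions of ``role`` in body cells intersecting grid row ``row``."""
    pattern = RSID_RE if role == "rsid" else PVALUE_RE
    out = []
    for cell in table.cells:
        if cell.is_header or not cell.text:
            continue
        if not (cell.row <= row < cell.row + cell.rowspan):
            continue
        for m in pattern.finditer(cell.text):
            raw = m.group()
            value = None
            if role == "pvalue":
                try:
                    value = normalize_pvalue(raw)
                except (ValueError, OverflowError):
                    continue
                if not (0.0 < value <= 1.0):
                    continue
            out.append(
                Mention(
                    doc.doc_id, _cell_id(table, cell), m.start(), m.end(),
                    raw, role, value=value,
                )
            )
    return out


def generate_rsid_pvalue_relations(doc: DocumentModel) -> list[CandidateRelation]:
    """Pair the unique rsid of each table row with every p-value in the row.

    Rows holding two or more distinct rsid mentions produce nothing: a
    multi-variant row (e.g. a haplotype listing) is ambiguous about which
    variant each p-value belongs to.
    """
    out = []
    for table in doc.tables:
        for row in range(table.n_rows):
            rsids = _row_mentions(doc, table, row, "rsid")
            # a rowspan cell revisits rows; count distinct mention objects
            rsids = list(dict.fromkeys(rsids))
            if len(rsids) != 1:
                continue
            for pv in dict.fromkeys(_row_mentions(doc, table, row, "pvalue")):
                out.append(
                    CandidateRelation(
                        "rsid_pvalue", rsids[0], pv, table.table_id, row
                    )
                )
    # a cell spanning multiple rows generates the same pair repeatedly
    return list(dict.fromkeys(out))


_PHENO_HEADER_KEYWORDS = ("phenotype", "trait", "outcome")


def generate_phenotype_pvalue_relations(doc: DocumentModel) -> list[CandidateRelation]:
    """Phenotype-cell candidates paired with aligned p-value mentions.

    A body cell is a phenotype candidate when its governing column header
    contains "phenotype", "trait" or "outcome" (case-insensitive substring).
    """
    out = []
    for table in doc.tables:
        for cell in table.cells:
            if cell.is_header or not cell.text:
                continue
            header = cell.column_header_text.lower()
            if not any(k in header for k in _PHENO_HEADER_KEYWORDS):
                continue
            pheno = Mention(
                doc.doc_id, _cell_id(table, cell), 0, len(cell.text),
                cell.text, "phenotype",
            )
            for row in range(cell.row, cell.row + cell.rowspan):
                for pv in _row_mentions(doc, table, row, "pvalue"):
                    out.append(
                        CandidateRelation(
                            "phenotype_pvalue", pheno, pv, table.table_id, row,
                            header_text=cell.column_header_text,
                        )
                    )
    return list(dict.fromkeys(out))


# ---------------------------------------------------------------------------
# acronym/expansion candidates
# ---------------------------------------------------------------------------

_ACRO_TEXT_RE = re.compile(r"\(\s*(?P<acro>\w{2,10})\s*\)")
_EXPANSION_HEADERS = ("phenotype", "trait", "description")
_ACRONYM_HEADERS = ("abbreviation", "acronym", "phenotype")


def _text_acronym_pairs(doc: DocumentModel) -> list[CandidateRelation]:
    """"<expansion words> (<ACRO>)" pattern in sentences.

    The expansion is the up-to-six preceding words (excluding sentence
    punctuation); ACRO is 2-10 word characters with at least one capital.
    """
    out = []
    for sent in doc.sentences():
        text = sent.text
        for m in _ACRO_TEXT_RE.finditer(text):
            acro = m.group("acro")
            if not any(ch.isupper() for ch in acro):
                continue  # rejects years "(2019)" and lowercase asides
            preceding = text[: m.start()].rstrip()
            words = list(_WORD_RE.finditer(preceding))
            if not words:
                continue
            # prefer the longest preceding-word window whose initials spell
            # the acronym; otherwise fall back to one word per letter
            acro_letters = re.sub(r"[^A-Za-z0-9]", "", acro).lower()
            n_words = None
            for k in range(min(6, len(words)), 0, -1):
                initials = "".join(
                    w.group()[0].lower() for w in words[-k:]
                )
                if initials == acro_letters:
                    n_words = k
                    break
            if n_words is None:
                n_words = min(len(words), max(1, len(acro_letters)))
            start = words[-n_words].start()
            expansion = preceding[start:].strip(" ,;:")
            if not expansion:
                continue
            exp_m = Mention(
                doc.doc_id, sent.sent_id, start, start + len(expansion),
                expansion, "expansion",
            )
            acro_m = Mention(
                doc.doc_id, sent.sent_id, m.start("acro"), m.end("acro"),
                acro, "acronym",
            )
            out.append(CandidateRelation("acronym_expansion", acro_m, exp_m))
    return out


def _header_matches(header: str, keywords: tuple[str, ...]) -> bool:
    h = header.lower()
    return any(k in h for k in keywords)


def _table_acronym_pairs(doc: DocumentModel) -> list[CandidateRelation]:
    """Aligned cell pairs from definition tables (column- or row-oriented)."""
    out = []
    for table in doc.tables:
        grid = table.grid()
        headers = [c for c in table.cells if c.is_header and c.text]
        # column-oriented: headers in top rows label columns
        acro_cols = [c.col for c in headers if _header_matches(c.text, _ACRONYM_HEADERS)]
        exp_cols = [c.col for c in headers if _header_matches(c.text, _EXPANSION_HEADERS)]
        for ac in acro_cols:
            for ec in exp_cols:
                if ac == ec:
                    continue
                for row in range(table.n_rows):
                    a = grid.get((row, ac))
                    e = grid.get((row, ec))
                    if a is None or e is None or a.is_header or e.is_header:
                        continue
                    if a.text and e.text:
                        out.append(_pair(doc, table, a, e, row))
        # row-oriented: first-column cells label rows
        first_col = [grid.get((r, 0)) for r in range(table.n_rows)]
        acro_rows = [
            r for r, c in enumerate(first_col)
            if c is not None and _header_matches(c.text, _ACRONYM_HEADERS)
        ]
        exp_rows = [
            r for r, c in enumerate(first_col)
            if c is not None and _header_matches(c.text, _EXPANSION_HEADERS)
        ]
        for ar in acro_rows:
            for er in exp_rows:
                if ar == er:
                    continue
                for col in range(1, table.n_cols):
                    a = grid.get((ar, col))
                    e = grid.get((er, col))
                    if a is None or e is None:
                        continue
                    if a.text and e.text:
                        out.append(_pair(doc, table, a, e, ar))
    return list(dict.fromkeys(out))


def _pair(doc: DocumentModel, table: Table, a: Cell, e: Cell, row: int) -> CandidateRelation:
    return CandidateRelation(
        "acronym_expansion",
        Mention(doc.doc_id, _cell_id(table, a), 0, len(a.text), a.text, "acronym"),
        Mention(doc.doc_id, _cell_id(table, e), 0, len(e.text), e.text, "expansion"),
        table.table_id,
        row,
    )


def generate_acronym_candidates(doc: DocumentModel) -> list[CandidateRelation]:
    """Acronym/expansion pairs from definition tables and running text."""
    return _table_acronym_pairs(doc) + _text_acronym_pairs(doc)
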