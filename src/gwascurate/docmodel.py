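"""Hierarchical document model for JATS/PMC-style full-text XML.

Parses an article into a :class:`DocumentModel` — title, abstract and body
sentences plus fully materialized table grids — which every downstream
extraction stage consumes.  Table cells are expanded over their row/col
spans into a dense grid so that "horizontally aligned" has a single,
unambiguous meaning for relation candidates.

Part-of-speech information is reduced to a per-token noun flag produced by
a rule-based tagger (closed-class word list + suffix heuristics); only that
flag is consumed downstream.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "Token",
    "Sentence",
    "Cell",
    "Table",
    "DocumentModel",
    "parse_document",
    "tokenize_and_tag",
    "split_sentences",
    "row_of",
]


@dataclass(frozen=True)
class Token:
    text: str
    start: int  # char offset into the sentence text
    end: int
    is_noun: bool


@dataclass
class Sentence:
    sent_id: str
    container: str  # one of {"title", "abstract", "body", "table-cell"}
    text: str
    tokens: list[Token] = field(default_factory=list)


@dataclass
class Cell:
    row: int
    col: int
    rowspan: int
    colspan: int
    is_header: bool
    text: str
    column_header_text: str = ""

    def covers(self) -> set[tuple[int, int]]:
        """Grid positions occupied by this cell after span expansion."""
        return {
            (r, c)
            for r in range(self.row, self.row + self.rowspan)
            for c in range(self.col, self.col + self.colspan)
        }


@dataclass
class Table:
    table_id: str
    cells: list[Cell]
    n_rows: int
    n_cols: int

    def grid(self) -> dict[tuple[int, int], Cell]:
        g: dict[tuple[int, int], Cell] = {}
        for cell in self.cells:
            for pos in cell.covers():
                g[pos] = cell
        return g


@dataclass
class DocumentModel:
    doc_id: str
    title: list[Sentence]
    abstract: list[Sentence]
    body: list[Sentence]
    tables: list[Table]

    def sentences(self) -> list[Sentence]:
        return [*self.title, *self.abstract, *self.body]

    def to_json(self) -> str:
        """Debug serialization; stable for byte-identical input."""

        def sent(s: Sentence) -> dict:
            return {
                "sent_id": s.sent_id,
                "container": s.container,
                "text": s.text,
                "tokens": [[t.text, t.start, t.end, t.is_noun] for t in s.tokens],
            }

        payload = {
            "doc_id": self.doc_id,
            "title": [sent(s) for s in self.title],
            "abstract": [sent(s) for s in self.abstract],
            "body": [sent(s) for s in self.body],
            "tables": [
                {
                    "table_id": t.table_id,
                    "n_rows": t.n_rows,
                    "n_cols": t.n_cols,
                    "cells": [
                        {
                            "row": c.row,
                            "col": c.col,
                            "rowspan": c.rowspan,
                            "colspan": c.colspan,
                            "is_header": c.is_header,
                            "text": c.text,
                            "column_header_text": c.column_header_text,
                        }
                        for c in t.cells
                    ],
                }
                for t in self.tables
            ],
        }
        return json.dumps(payload, sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# Tokenization and noun tagging
# ---------------------------------------------------------------------------

# Closed-class / function words: never nouns.  Deliberately small — anything
# open-class and alphabetic defaults to noun-ish unless a verb/adjective
# suffix rules it out, which suits phenotype terms (mostly noun phrases).
_FUNCTION_WORDS = frozenset(
    """
    a an the this that these those some any each every no
    and or but nor so yet if then than because while although though
    of in on at by for with without from to into onto over under between
    among through during before after above below up down out off about
    against across around near
    i you he she it we they me him her us them my your his its our their
    is are was were be been being am do does did done have has had having
    will would shall should may might must can could not
    as very too also only just more most less least such both either neither
    there here when where why how what which who whom whose
    et al eg ie vs versus
    """.split()
)

# Suffixes typical of adjectives/adverbs/verb forms → not a noun.
_NON_NOUN_SUFFIXES = ("ly", "ing", "ed", "ous", "ive", "able", "ible", "al", "ic")
# Noun-forming suffixes override the list above ("clinical" stays non-noun,
# "aggregation"/"activity" stay nouns).
_NOUN_SUFFIXES = (
    "tion", "sion", "ment", "ness", "ity", "ism", "ase", "osis", "emia",
    "itis", "oma", "cyte", "gen", "ol", "ine", "ide", "ure", "ance", "ence",
)

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


def _is_noun(token: str) -> bool:
    if not any(ch.isalpha() for ch in token):
        return False
    low = token.lower()
    if low in _FUNCTION_WORDS:
        return False
    if low.endswith(_NOUN_SUFFIXES):
        return True
    if low.endswith(_NON_NOUN_SUFFIXES):
        return False
    return True


def tokenize_and_tag(text: str) -> list[Token]:
    """Tokenize one sentence and flag probable nouns.

    Tokens cover the text exactly (whitespace recoverable from offsets), so
    concatenating ``text[t.start:t.end]`` with the original gaps
    reconstructs the sentence.
    """
    return [
        Token(m.group(), m.start(), m.end(), _is_noun(m.group()))
        for m in _TOKEN_RE.finditer(text)
    ]


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

_ABBREVIATIONS = ("e.g.", "i.e.", "vs.", "et al.", "etc.", "cf.", "ca.", "Fig.", "fig.")
_SPLIT_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9])")


def split_sentences(text: str) -> list[str]:
    """Split on sentence-final punctuation followed by whitespace + capital.

    A small abbreviation list protects "e.g.", "vs.", "et al." etc. by
    masking their dots before splitting.
    """
    masked = text
    for abbr in _ABBREVIATIONS:
        masked = masked.replace(abbr, abbr.replace(".", "\x00"))
    parts = []
    prev = 0
    for m in _SPLIT_RE.finditer(masked):
        parts.append(text[prev:m.start()].strip())
        prev = m.end()
    parts.append(text[prev:].strip())
    return [p for p in parts if p]


# ---------------------------------------------------------------------------
# XML parsing
# ---------------------------------------------------------------------------

def _local(tag) -> str:
    if not isinstance(tag, str):
        return ""
    return tag.rsplit("}", 1)[-1]


def _text_of(elem) -> str:
    return re.sub(r"\s+", " ", "".join(elem.itertext())).strip()


def _parse_table(elem, table_id: str) -> Table:
    """Expand a <table> element (thead/tbody/tr/td|th) into a dense grid."""
    rows: list[list[etree._Element]] = []
    header_rows: set[int] = set()
    idx = 0
    for section in elem.iter():
        if _local(section.tag) != "tr":
            continue
        cells = [ch for ch in section if _local(ch.tag) in ("td", "th")]
        rows.append(cells)
        ancestors = {_local(a.tag) for a in section.iterancestors()}
        if "thead" in ancestors or all(_local(c.tag) == "th" for c in cells if cells):
            header_rows.add(idx)
        idx += 1

    # standard HTML-table span expansion: walk rows, skipping occupied slots
    occupied: set[tuple[int, int]] = set()
    cells: list[Cell] = []
    n_cols = 0
    for r, row_elems in enumerate(rows):
        c = 0
        for cell_elem in row_elems:
            while (r, c) in occupied:
                c += 1
            try:
                rowspan = max(1, int(cell_elem.get("rowspan", "1")))
                colspan = max(1, int(cell_elem.get("colspan", "1")))
            except ValueError:
                rowspan = colspan = 1

            def region_clear(rs: int, cs: int) -> bool:
                return not any(
                    (rr, cc) in occupied
                    for rr in range(r, r + rs)
                    for cc in range(c, c + cs)
                )

            # pathological span combinations can collide with cells placed
            # earlier; shrink until the rectangle is free (first col, then row)
            while colspan > 1 and not region_clear(rowspan, colspan):
                colspan -= 1
            while rowspan > 1 and not region_clear(rowspan, colspan):
                rowspan -= 1
            cell = Cell(
                row=r,
                col=c,
                rowspan=rowspan,
                colspan=colspan,
                is_header=(r in header_rows or _local(cell_elem.tag) == "th"),
                text=_text_of(cell_elem),
            )
            occupied.update(cell.covers())
            cells.append(cell)
            c += colspan
        n_cols = max(n_cols, c)
    n_rows = len(rows)

    # clamp spans that stick out past the table edge
    for cell in cells:
        cell.rowspan = min(cell.rowspan, n_rows - cell.row)
        cell.colspan = min(cell.colspan, n_cols - cell.col)

    # ragged rows: pad with empty filler cells so the grid is complete
    for r in range(n_rows):
        for c in range(n_cols):
            if (r, c) not in occupied:
                filler = Cell(r, c, 1, 1, r in header_rows, "")
                occupied.add((r, c))
                cells.append(filler)

    # column_header_text: header cell texts vertically above, top-to-bottom
    grid = {}
    for cell in cells:
        for pos in cell.covers():
            grid[pos] = cell
    for cell in cells:
        if cell.is_header:
            continue
        parts: list[str] = []
        seen_ids: set[int] = set()  # a rowspan header appears once, not per row
        for r in range(cell.row):
            for c in range(cell.col, cell.col + cell.colspan):
                above = grid.get((r, c))
                if (
                    above is not None
                    and above.is_header
                    and above.text
                    and id(above) not in seen_ids
                ):
                    seen_ids.add(id(above))
                    parts.append(above.text)
        cell.column_header_text = " ".join(parts)

    cells.sort(key=lambda cl: (not cl.is_header, cl.row, cl.col))
    return Table(table_id=table_id, cells=cells, n_rows=n_rows, n_cols=n_cols)


def parse_document(xml_bytes: bytes, doc_id: str | None = None) -> DocumentModel:
    """Parse JATS/PMC-like XML bytes into a :class:`DocumentModel`.

    Recognized elements: ``article-title``, ``abstract``, body ``p``
    paragraphs, ``table-wrap``/``table`` with ``thead``/``tbody``/``tr`` and
    ``td``/``th`` carrying ``rowspan``/``colspan``.  Unknown elements are
    skipped with a logged warning; a missing title yields an empty title
    list plus a warning, never an error.

    Raises
    ------
    ValueError
        if the bytes are not well-formed XML (message includes the
        reported parse position).
    """
    try:
        root = etree.fromstring(xml_bytes)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed XML: {exc}") from exc

    # document id: explicit arg > <article-id pub-id-type="pmid"> > attribute
    if doc_id is None:
        doc_id = ""
        for elem in root.iter():
            if _local(elem.tag) == "article-id" and elem.get("pub-id-type") == "pmid":
                doc_id = _text_of(elem)
                break
        if not doc_id:
            doc_id = root.get("id", "") or "doc"

    title_sents: list[Sentence] = []
    abstract_sents: list[Sentence] = []
    body_sents: list[Sentence] = []
    tables: list[Table] = []

    def add_sentences(bucket: list[Sentence], container: str, text: str) -> None:
        for piece in split_sentences(text):
            sid = f"{container}-{len(bucket)}"
            bucket.append(
                Sentence(sid, container, piece, tokenize_and_tag(piece))
            )

    for elem in root.iter():
        tag = _local(elem.tag)
        if tag == "article-title":
            add_sentences(title_sents, "title", _text_of(elem))
        elif tag == "abstract":
            add_sentences(abstract_sents, "abstract", _text_of(elem))
        elif tag == "table":
            tables.append(_parse_table(elem, f"T{len(tables)}"))
        elif tag == "p":
            # only body paragraphs: skip <p> nested in abstract or tables
            ancestors = {_local(a.tag) for a in elem.iterancestors()}
            if not ancestors & {"abstract", "table", "table-wrap"}:
                add_sentences(body_sents, "body", _text_of(elem))

    if not title_sents:
        logger.warning("document %s has no <article-title>; empty title", doc_id)

    return DocumentModel(
        doc_id=doc_id,
        title=title_sents,
        abstract=abstract_sents,
        body=body_sents,
        tables=tables,
    )


def row_of(cell: Cell, table: Table) -> list[Cell]:
    """All cells horizontally aligned with ``cell`` in ``table``.

    A cell is aligned if its expanded row range intersects the query
    cell's; the result includes the query cell itself and is ordered by
    column (ties by row).
    """
    if not any(c is cell for c in table.cells):
        raise ValueError("cell does not belong to table")
    lo, hi = cell.row, cell.row + cell.rowspan  # half-open
    out = [
        c
        for c in table.cells
        if c.row < hi and c.row + c.rowspan > lo
    ]
    out.sort(key=lambda c: (c.col, c.row))
    return out
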