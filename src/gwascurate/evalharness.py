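"""Evaluation against a human-curated reference catalog.

A reference association (pmid, rsid, phenotype, p-value) counts as
*recovered* when some extracted record shares its pmid and rsid and the
extracted phenotype maps to the reference phenotype at the requested
level.  Phenotype equivalence is externalized in a hand-made mapping table
(extracted term, reference term, level ∈ {exact, approximate}); identical
strings (after case folding and whitespace normalization) are always an
exact match without a table entry.  "Approximate" means the extracted term
conceptually contains the reference term while being less specific
(e.g. smoking behaviors vs. cigarette packs per day); requesting the
approximate level accepts exact matches too.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "ReferenceRecord",
    "PhenotypeMapping",
    "load_reference",
    "match",
    "estimate_phenotype_precision",
    "error_breakdown",
]

_RSID_RE = re.compile(r"^rs[1-9][0-9]{2,}$", re.IGNORECASE)
_LEVELS = ("exact", "approximate")


@dataclass(frozen=True)
class ReferenceRecord:
    pmid: str
    rsid: str
    phenotype: str
    p_value: float

    def __post_init__(self):
        if not _RSID_RE.match(self.rsid):
            raise ValueError(f"invalid rsid in reference: {self.rsid!r}")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"reference p-value outside (0, 1]: {self.p_value}")


def _norm(s: str) -> str:
    return re.sub(r"\s+", " ", s.strip().lower())


@dataclass
class PhenotypeMapping:
    """(extracted, reference) → level lookup, case-insensitive."""

    entries: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self):
        normed = {}
        for (a, b), level in self.entries.items():
            if level not in _LEVELS:
                raise ValueError(f"mapping level must be exact/approximate: {level!r}")
            normed[(_norm(a), _norm(b))] = level
        self.entries = normed

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypeMapping":
        """3-column TSV: extracted term, reference term, level."""
        entries = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ext, ref, level = line.split("\t")[:3]
            entries[(ext, ref)] = level
        return cls(entries)

    def level(self, extracted: str, reference: str) -> str:
        """'exact', 'approximate' or 'none' for one phenotype pair."""
        a, b = _norm(extracted), _norm(reference)
        if a == b:
            return "exact"
        return self.entries.get((a, b), "none")


def load_reference(path: str | Path, columns: dict[str, str] | None = None) -> list[ReferenceRecord]:
    """Read a reference catalog TSV (GWAS Catalog-style shape).

    ``columns`` maps our field names to the file's column names when they
    differ, e.g. ``{"rsid": "SNPS", "phenotype": "DISEASE/TRAIT"}``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    colmap = {"pmid": "pmid", "rsid": "rsid", "phenotype": "phenotype", "p_value": "p_value"}
    colmap.update(columns or {})
    return [
        ReferenceRecord(
            str(row[colmap["pmid"]]),
            str(row[colmap["rsid"]]),
            str(row[colmap["phenotype"]]),
            float(row[colmap["p_value"]]),
        )
        for _, row in df.iterrows()
    ]


def _extracted_phenotypes(rec) -> list[str]:
    """All phenotype strings an extracted record offers for matching."""
    out = []
    for attr in ("resolved_phenotype", "precise_phenotype"):
        v = getattr(rec, attr, None)
        if v:
            out.append(v)
    out.extend(getattr(rec, "simple_phenotypes", ()) or ())
    return out


def _match_level(rec, ref: ReferenceRecord, mapping: PhenotypeMapping) -> str:
    """Best phenotype agreement level between one record and one reference."""
    best = "none"
    for pheno in _extracted_phenotypes(rec):
        lvl = mapping.level(pheno, ref.phenotype)
        if lvl == "exact":
            return "exact"
        if lvl == "approximate":
            best = "approximate"
    return best


def match(
    extracted,
    reference: list[ReferenceRecord],
    mapping: PhenotypeMapping | None = None,
    level: str = "approximate",
) -> tuple[list[tuple], float]:
    """Recovered (extracted, reference) pairs and recall at a level.

    ``level='approximate'`` accepts exact matches as well; ``'exact'``
    requires full phenotype agreement.
    """
    if level not in _LEVELS:
        raise ValueError(f"level must be one of {_LEVELS}")
    mapping = mapping or PhenotypeMapping()
    accepted = {"exact"} if level == "exact" else {"exact", "approximate"}
    by_key: dict[tuple[str, str], list] = {}
    for rec in extracted:
        by_key.setdefault((str(rec.pmid), rec.rsid.lower()), []).append(rec)

    pairs = []
    recovered = 0
    for ref in reference:
        hit = None
        for rec in by_key.get((str(ref.pmid), ref.rsid.lower()), []):
            if _match_level(rec, ref, mapping) in accepted:
                hit = rec
                break
        if hit is not None:
            recovered += 1
            pairs.append((hit, ref))
    recall = recovered / len(reference) if reference else float("nan")
    return pairs, recall


def estimate_phenotype_precision(
    extracted,
    reference: list[ReferenceRecord],
    mapping: PhenotypeMapping | None = None,
    level: str = "approximate",
) -> float:
    """Phenotype precision over catalog-confirmed variants.

    Restrict to extracted records whose (pmid, rsid) occurs in the
    reference in *some* relation — the variant is confirmed, regardless of
    phenotype — then return the fraction of those whose phenotype also
    agrees at the requested level.  Raises when no extracted record is
    confirmed (the estimate is undefined).
    """
    mapping = mapping or PhenotypeMapping()
    accepted = {"exact"} if level == "exact" else {"exact", "approximate"}
    refs_by_key: dict[tuple[str, str], list[ReferenceRecord]] = {}
    for ref in reference:
        refs_by_key.setdefault((str(ref.pmid), ref.rsid.lower()), []).append(ref)

    confirmed = 0
    correct = 0
    for rec in extracted:
        refs = refs_by_key.get((str(rec.pmid), rec.rsid.lower()))
        if not refs:
            continue
        confirmed += 1
        if any(_match_level(rec, ref, mapping) in accepted for ref in refs):
            correct += 1
    if confirmed == 0:
        raise ValueError(
            "phenotype precision undefined: no extracted (pmid, rsid) is "
            "confirmed by the reference"
        )
    return correct / confirmed


def error_breakdown(
    extracted,
    reference: list[ReferenceRecord],
    mapping: PhenotypeMapping | None = None,
) -> dict[str, int]:
    """Partition the reference into four mutually exclusive outcomes.

    recovered_exact / recovered_approx / wrong_phenotype (variant matched,
    phenotype did not map) / missed_variant (no extracted record shares the
    pmid+rsid).  The four counts always sum to ``len(reference)``.
    """
    mapping = mapping or PhenotypeMapping()
    by_key: dict[tuple[str, str], list] = {}
    for rec in extracted:
        by_key.setdefault((str(rec.pmid), rec.rsid.lower()), []).append(rec)

    counts = {
        "recovered_exact": 0,
        "recovered_approx": 0,
        "wrong_phenotype": 0,
        "missed_variant": 0,
    }
    for ref in reference:
        recs = by_key.get((str(ref.pmid), ref.rsid.lower()), [])
        if not recs:
            counts["missed_variant"] += 1
            continue
        levels = {_match_level(rec, ref, mapping) for rec in recs}
        if "exact" in levels:
            counts["recovered_exact"] += 1
        elif "approximate" in levels:
            counts["recovered_approx"] += 1
        else:
            counts["wrong_phenotype"] += 1
    return counts
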