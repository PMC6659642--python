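"""Linkage-disequilibrium novelty filter.

Decides which extracted variants are genuinely new relative to a curated
catalog: a variant correlated at r² above threshold with a known variant
reported in the same paper is tagging the same signal, not a discovery.
r² is the squared Pearson correlation of allele-dosage vectors (0/1/2)
over a shared genotype panel — no phasing required.

Two passes per paper: (1) drop extracted variants in LD with any known
variant of that paper; (2) greedily deduplicate the survivors against each
other (ordered by ascending p-value then rsid) so a cluster of mutually
linked novel variants is reported once.  Variants absent from the panel
cannot be assessed and are retained with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DosagePanel", "LDResult", "compute_r2", "filter_novel", "load_panel"]


@dataclass(frozen=True)
class LDResult:
    rsid: str
    best_known: str | None
    r2: float | None
    in_panel: bool
    retained: bool
    dropped_by: str | None = None  # "known" | "novel" | None


class DosagePanel:
    """rsid → dosage vector (0/1/2) over a fixed sample set."""

    def __init__(self, dosages: dict[str, np.ndarray]):
        self._d: dict[str, np.ndarray] = {}
        length = None
        for rsid, vec in dosages.items():
            vec = np.asarray(vec, dtype=float)
            if length is None:
                length = vec.size
            elif vec.size != length:
                raise ValueError("all dosage vectors must share sample count")
            if not np.isin(vec, (0, 1, 2)).all():
                raise ValueError(f"dosages for {rsid} not in {{0,1,2}}")
            self._d[rsid.lower()] = vec
        self.n_samples = length or 0

    def __contains__(self, rsid: str) -> bool:
        return rsid.lower() in self._d

    def __getitem__(self, rsid: str) -> np.ndarray:
        return self._d[rsid.lower()]

    def rsids(self) -> list[str]:
        return sorted(self._d)


def load_panel(path: str | Path) -> DosagePanel:
    """Load a dosage panel from VCF (GT-derived dosages) or TSV matrix.

    TSV shape: first column rsid, remaining columns per-sample dosages.
    VCF: alt-allele dosage = number of non-reference alleles in GT.
    """
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz", ".bcf") or path.name.endswith(".vcf.gz"):
        import pysam

        dosages: dict[str, np.ndarray] = {}
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                if not rec.id:
                    continue
                vec = []
                for sample in rec.samples.values():
                    gt = sample.get("GT") or ()
                    vec.append(sum(1 for a in gt if a not in (None, 0)))
                dosages[rec.id] = np.array(vec, dtype=float)
        return DosagePanel(dosages)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DosagePanel({str(r): df.loc[r].to_numpy(dtype=float) for r in df.index})


def compute_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, clamped to [0,1].

    Symmetric, and invariant under allele flip (d → 2 − d).  Raises when
    either vector has zero variance (r² undefined for monomorphic sites).
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.size != b.size:
        raise ValueError("dosage vectors differ in length")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("r2 undefined: zero-variance dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(1.0, max(0.0, r * r)))


def filter_novel(
    extracted_rsids: list[str],
    known_rsids: list[str],
    panel: DosagePanel,
    threshold: float = 0.5,
    pvalues: dict[str, float] | None = None,
) -> tuple[list[str], list[LDResult]]:
    """Within-paper two-pass LD filter.

    Pass 1 removes extracted variants with r² > ``threshold`` against any
    known variant of the paper; pass 2 orders the survivors by ascending
    p-value (then rsid) and greedily removes each variant in LD with an
    earlier retained one.  Variants missing from the panel are retained
    and flagged ``in_panel=False``.

    Returns (retained rsids, per-variant LDResult diagnostics).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    pvalues = pvalues or {}

    def order_key(rsid: str):
        return (pvalues.get(rsid, 1.0), rsid.lower())

    results: list[LDResult] = []
    survivors: list[str] = []
    for rsid in sorted(dict.fromkeys(extracted_rsids), key=order_key):
        if rsid not in panel:
            results.append(LDResult(rsid, None, None, False, True))
            survivors.append(rsid)
            continue
        vec = panel[rsid]
        best_known, best_r2 = None, -1.0
        for known in known_rsids:
            if known.lower() == rsid.lower():
                best_known, best_r2 = known, 1.0
                break
            if known not in panel:
                continue
            try:
                r2 = compute_r2(vec, panel[known])
            except ValueError:
                continue
            if r2 > best_r2:
                best_known, best_r2 = known, r2
        if best_known is not None and best_r2 > threshold:
            results.append(LDResult(rsid, best_known, best_r2, True, False, "known"))
        else:
            results.append(
                LDResult(rsid, best_known, best_r2 if best_known else None, True, True)
            )
            survivors.append(rsid)

    # pass 2: deduplicate survivors against each other, in order
    retained: list[str] = []
    final: list[str] = []
    by_rsid = {r.rsid: r for r in results}
    for rsid in survivors:
        if rsid not in panel:
            final.append(rsid)
            retained.append(rsid)
            continue
        clash = None
        for earlier in retained:
            if earlier not in panel:
                continue
            try:
                r2 = compute_r2(panel[rsid], panel[earlier])
            except ValueError:
                continue
            if r2 > threshold:
                clash = (earlier, r2)
                break
        if clash is None:
            final.append(rsid)
            retained.append(rsid)
        else:
            old = by_rsid[rsid]
            by_rsid[rsid] = LDResult(
                rsid, clash[0], clash[1], True, False, "novel"
            )
    results = [by_rsid[r.rsid] for r in results]
    return final, results
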