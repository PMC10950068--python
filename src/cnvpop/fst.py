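"""Per-locus Fst between two populations and the empirical top-tail scan.

The statistic is Fst = (Ht - Hs) / Ht with Hs the unweighted mean of the two
within-population expected heterozygosities, Hs = (2 p1 q1 + 2 p2 q2) / 2,
and Ht the expected heterozygosity at the unweighted mean frequency,
Ht = 2 pbar qbar with pbar = (p1 + p2) / 2. With equal weights this is Nei's
Gst for two demes and is algebraically equal to (p1 - p2)^2 / (4 pbar qbar).
Fst is undefined (never silently zero) where Ht = 0, i.e. where the variant
is absent or fixed in both populations.

Selection candidates are the empirical top fraction (default 1%) of defined
Fst values; no multiple-testing machinery is involved — this is an
outlier-tail scan, not a hypothesis test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import CNVLocus, GenotypeMatrix, chrom_sort_key

logger = logging.getLogger(__name__)


@dataclass
class FstRecord:
    """Per-locus frequencies, heterozygosities and differentiation."""

    id: str
    p1: float
    p2: float
    hs: float
    ht: float
    fst: float  # NaN when undefined
    chrom: str = ""
    start: int = 0
    end: int = 0

    @property
    def defined(self) -> bool:
        return not math.isnan(self.fst)


@dataclass
class ScanResult:
    records: List[FstRecord]
    selected_ids: List[str]
    threshold: Optional[float]  # minimum Fst among selected; None if none selected
    top_fraction: float
    n_defined: int


def fst_from_frequencies(p1, p2):
    """Vectorised Fst = (Ht - Hs)/Ht; NaN where Ht = 0 or a frequency is NaN."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    finite = ~(np.isnan(p1) | np.isnan(p2))
    if np.any((p1[finite] < 0) | (p1[finite] > 1) | (p2[finite] < 0) | (p2[finite] > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
    pbar = (p1 + p2) / 2.0
    ht = 2 * pbar * (1 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / ht, np.nan)
    return fst


def locus_fst(p1: float, p2: float, id: str = "") -> FstRecord:
    """Fst record for a single locus from the two population frequencies."""
    for p in (p1, p2):
        if math.isnan(p) or not (0.0 <= p <= 1.0):
            raise ValueError(f"frequency {p} outside [0, 1]")
    hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
    pbar = (p1 + p2) / 2.0
    ht = 2 * pbar * (1 - pbar)
    fst = (ht - hs) / ht if ht > 0 else float("nan")
    return FstRecord(id=id, p1=p1, p2=p2, hs=hs, ht=ht, fst=fst)


def scan(matrix: GenotypeMatrix, pop_a: str, pop_b: str) -> List[FstRecord]:
    """One FstRecord per locus from per-population allele frequencies.

    Loci where either population has no called genotype get an undefined Fst.
    """
    from .vcfio import allele_frequencies

    if pop_a == pop_b:
        raise ValueError("scan requires two distinct populations")
    fa = allele_frequencies(matrix, pop_a)
    fb = allele_frequencies(matrix, pop_b)
    hs = (2 * fa * (1 - fa) + 2 * fb * (1 - fb)) / 2.0
    pbar = (fa + fb) / 2.0
    ht = 2 * pbar * (1 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / ht, np.nan)
    records = []
    for j, locus in enumerate(matrix.loci):
        records.append(
            FstRecord(
                id=locus.id,
                p1=float(fa[j]),
                p2=float(fb[j]),
                hs=float(hs[j]) if not np.isnan(hs[j]) else float("nan"),
                ht=float(ht[j]) if not np.isnan(ht[j]) else float("nan"),
                fst=float(fst[j]),
                chrom=locus.chrom,
                start=locus.start,
                end=locus.end,
            )
        )
    return records


def select_top(records: Sequence[FstRecord], top_fraction: float = 0.01) -> ScanResult:
    """Empirical top-tail selection over the defined-Fst records.

    n_selected = floor(top_fraction * N_defined); ties at the cut are broken
    by (Fst descending, chrom, start ascending) and the cut is exact. The
    threshold is the Fst of the last selected record.
    """
    if not (0.0 < top_fraction < 1.0):
        raise ValueError("top_fraction must be in (0, 1)")
    defined = [r for r in records if r.defined]
    if not defined:
        raise ValueError("no locus has a defined Fst")
    n_selected = int(math.floor(top_fraction * len(defined)))
    ranked = sorted(defined, key=lambda r: (-r.fst, chrom_sort_key(r.chrom), r.start))
    chosen = ranked[:n_selected]
    threshold = chosen[-1].fst if chosen else None
    return ScanResult(
        records=list(records),
        selected_ids=[r.id for r in chosen],
        threshold=threshold,
        top_fraction=top_fraction,
        n_defined=len(defined),
    )


def selected_gene_overlap(result: ScanResult, model, loci: Sequence[CNVLocus], flank: int = 1000) -> List[str]:
    """Unique gene names whose transcript span (+- flank) intersects a selected locus.

    Ordered by the gene's genomic position (chrom, start).
    """
    by_id = {l.id: l for l in loci}
    selected = [by_id[i] for i in result.selected_ids if i in by_id]
    hits = {}
    for tx in model.transcripts:
        for locus in selected:
            if locus.chrom != tx.chrom:
                continue
            if locus.start <= tx.end + flank and locus.end >= tx.start - flank:
                key = tx.gene
                pos = (chrom_sort_key(tx.chrom), tx.start)
                if key not in hits or pos < hits[key]:
                    hits[key] = pos
                break
    return [g for g, _ in sorted(hits.items(), key=lambda kv: kv[1])]


def manhattan_table(result: ScanResult) -> pd.DataFrame:
    """Plot-ready table: chrom, midpoint, Fst, selected flag; genome-sorted.

    Loci with undefined Fst are excluded (their count is logged).
    """
    selected = set(result.selected_ids)
    rows = []
    n_undefined = 0
    for r in result.records:
        if not r.defined:
            n_undefined += 1
            continue
        rows.append(
            {
                "chrom": r.chrom,
                "pos": (r.start + r.end) // 2,
                "fst": r.fst,
                "selected": r.id in selected,
                "id": r.id,
            }
        )
    if n_undefined:
        logger.info("excluded %d loci with undefined Fst from the table", n_undefined)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "fst", "selected", "id"])
    if len(df):
        df = df.sort_values(
            by=["chrom", "pos"], key=lambda col: col.map(chrom_sort_key) if col.name == "chrom" else col
        ).reset_index(drop=True)
    return df
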