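"""Independent oracles used by the test suite.

These deliberately avoid the package's interval indexes and vectorised code
paths: the annotation oracle enumerates literal base-position sets, and the
hypergeometric oracle sums binomial coefficients. They are only usable on
small instances, which is the point.
"""

from __future__ import annotations

from math import comb
from typing import List, Set

from cnvpop.annotate import Transcript
from cnvpop.core import CNVLocus


def _bases(start: int, end: int) -> Set[int]:
    return set(range(start, end + 1)) if end >= start else set()


def brute_force_classify(
    locus: CNVLocus, transcripts: List[Transcript], flank: int = 1000, splice: int = 2
) -> str:
    """Classify a CNV by exhaustive per-base feature enumeration."""
    cnv = _bases(locus.start, locus.end)
    cds: Set[int] = set()
    splice_b: Set[int] = set()
    nc: Set[int] = set()
    utr5: Set[int] = set()
    utr3: Set[int] = set()
    intron: Set[int] = set()
    up: Set[int] = set()
    down: Set[int] = set()
    for tx in transcripts:
        if tx.chrom != locus.chrom:
            continue
        exon_b = set()
        for s, e in tx.exons:
            exon_b |= _bases(s, e)
        # introns: bases between consecutive exons
        intron_tx: Set[int] = set()
        exs = sorted(tx.exons)
        for (s1, e1), (s2, e2) in zip(exs, exs[1:]):
            intron_tx |= _bases(e1 + 1, s2 - 1)
        if tx.biotype == "ncRNA":
            nc |= _bases(tx.start, tx.end)
        else:
            cds_span = _bases(tx.cds_start, tx.cds_end)
            cds |= exon_b & cds_span
            if tx.strand == "+":
                utr5 |= {b for b in exon_b if b < tx.cds_start}
                utr3 |= {b for b in exon_b if b > tx.cds_end}
            else:
                utr5 |= {b for b in exon_b if b > tx.cds_end}
                utr3 |= {b for b in exon_b if b < tx.cds_start}
            # splice windows: the `splice` intron bases adjacent to an exon base
            for b in sorted(intron_tx):
                near_exon = any(
                    (b - k in exon_b) or (b + k in exon_b) for k in range(1, splice + 1)
                )
                if near_exon:
                    splice_b.add(b)
            intron |= intron_tx
        if tx.strand == "+":
            up |= _bases(max(1, tx.start - flank), tx.start - 1)
            down |= _bases(tx.end + 1, tx.end + flank)
        else:
            up |= _bases(tx.end + 1, tx.end + flank)
            down |= _bases(max(1, tx.start - flank), tx.start - 1)

    if cnv & cds:
        return "exonic"
    if cnv & splice_b:
        return "splicing"
    if cnv & nc:
        return "ncRNA"
    hit5, hit3 = bool(cnv & utr5), bool(cnv & utr3)
    if hit5 and hit3:
        return "UTR5;UTR3"
    if hit5:
        return "UTR5"
    if hit3:
        return "UTR3"
    if cnv & intron:
        return "intronic"
    hit_up, hit_down = bool(cnv & up), bool(cnv & down)
    if hit_up and hit_down:
        return "upstream;downstream"
    if hit_up:
        return "upstream"
    if hit_down:
        return "downstream"
    return "intergenic"


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct summation of binomial coefficients."""
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)) / total
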