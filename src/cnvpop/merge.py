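"""Reciprocal-overlap merging of CNV call sets and sharing/coverage summaries.

Two calls are the same variant when they sit on the same chromosome, have
the same type, and each covers at least a reciprocal-overlap fraction
(default 50%) of the other — the community convention for SV equivalence.
Transitive chains are collapsed by single-linkage over start-sorted loci,
and the merged record spans the union interval, so coverage is monotone
non-decreasing under merging.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, FrozenSet, List, Sequence, Tuple

import pandas as pd
from scipy import stats

from .core import CNVLocus, chrom_sort_key

DEFAULT_RECIPROCAL_OVERLAP = 0.5


@dataclass
class MergedLocus:
    locus: CNVLocus
    sources: FrozenSet[str]  # population labels contributing to this record
    members: List[CNVLocus]  # the input calls collapsed into this record


@dataclass
class MergeResult:
    merged: List[MergedLocus]
    labels: Tuple[str, str]

    @property
    def loci(self) -> List[CNVLocus]:
        return [m.locus for m in self.merged]

    def counts(self) -> Dict[str, int]:
        a, b = self.labels
        shared = sum(1 for m in self.merged if m.sources == {a, b})
        only_a = sum(1 for m in self.merged if m.sources == {a})
        only_b = sum(1 for m in self.merged if m.sources == {b})
        return {"shared": shared, f"unique_{a}": only_a, f"unique_{b}": only_b}


def _reciprocal_overlap(x: CNVLocus, y: CNVLocus) -> float:
    """min of the two coverage fractions; 0 when disjoint."""
    ov = min(x.end, y.end) - max(x.start, y.start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / x.length, ov / y.length)


def merge_call_sets(
    set_a: Sequence[CNVLocus],
    set_b: Sequence[CNVLocus],
    reciprocal_overlap: float = DEFAULT_RECIPROCAL_OVERLAP,
    labels: Tuple[str, str] = ("A", "B"),
) -> MergeResult:
    """Merge two call sets into a nonredundant union with provenance.

    Loci merge iff same chrom, same svtype, and reciprocal overlap >= the
    threshold against at least one current cluster member (single-linkage,
    applied left-to-right over start-sorted loci). The merged span is the
    union interval. Every input locus lands in exactly one merged record.
    """
    if not (0.0 < reciprocal_overlap <= 1.0):
        raise ValueError("reciprocal_overlap must be in (0, 1]")
    tagged = [(l, labels[0]) for l in set_a] + [(l, labels[1]) for l in set_b]
    tagged.sort(key=lambda t: (t[0].sort_key(), t[1]))

    merged: List[MergedLocus] = []
    # open clusters per (chrom, svtype); only the last cluster can still grow
    open_cluster: Dict[Tuple[str, str], Tuple[List[CNVLocus], set]] = {}

    def close(key):
        members, sources = open_cluster.pop(key)
        start = min(m.start for m in members)
        end = max(m.end for m in members)
        chrom, svtype = key
        rep = CNVLocus(chrom, start, end, svtype, id=f"merged_{len(merged) + 1}")
        merged.append(MergedLocus(locus=rep, sources=frozenset(sources), members=members))

    for locus, src in tagged:
        key = (locus.chrom, locus.svtype)
        if key in open_cluster:
            members, sources = open_cluster[key]
            if any(_reciprocal_overlap(locus, m) >= reciprocal_overlap for m in members):
                members.append(locus)
                sources.add(src)
                continue
            close(key)
        open_cluster[key] = ([locus], {src})
    for key in list(open_cluster):
        close(key)

    merged.sort(key=lambda m: m.locus.sort_key())
    renamed = [
        MergedLocus(
            locus=CNVLocus(
                m.locus.chrom, m.locus.start, m.locus.end, m.locus.svtype, id=f"merged_{k + 1}"
            ),
            sources=m.sources,
            members=m.members,
        )
        for k, m in enumerate(merged)
    ]
    return MergeResult(merged=renamed, labels=labels)


def _round2(x) -> float:
    return float(Decimal(x).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def sharing_percentages(shared: int, unique_a: int, unique_b: int) -> Dict[str, float]:
    """Printed-style percentages (half-up, 2 decimals) of the merged total."""
    total = shared + unique_a + unique_b
    if total == 0:
        return {"shared": 0.0, "unique_a": 0.0, "unique_b": 0.0}
    return {
        "shared": _round2(Decimal(100 * shared) / Decimal(total)),
        "unique_a": _round2(Decimal(100 * unique_a) / Decimal(total)),
        "unique_b": _round2(Decimal(100 * unique_b) / Decimal(total)),
    }


def sharing_counts(result: MergeResult):
    """(shared, unique_a, unique_b, shared %, unique_a %) over the merged total."""
    a, b = result.labels
    c = result.counts()
    pct = sharing_percentages(c["shared"], c[f"unique_{a}"], c[f"unique_{b}"])
    return (c["shared"], c[f"unique_{a}"], c[f"unique_{b}"], pct["shared"], pct["unique_a"])


def _union_bp(loci: Sequence[CNVLocus]) -> int:
    """Total bp covered, collapsing same-type overlaps (no double counting)."""
    total = 0
    by_key: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for l in loci:
        by_key.setdefault((l.chrom, l.svtype), []).append((l.start, l.end))
    for ivs in by_key.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
    return total


def genome_summary(loci: Sequence[CNVLocus], genome_size_bp: int) -> Tuple[int, float]:
    """(total covered bp, percent of genome), union-collapsed per type."""
    if genome_size_bp <= 0:
        raise ValueError("genome_size_bp must be positive")
    total_bp = _union_bp(loci)
    ratio = _round2(Decimal(100 * total_bp) / Decimal(genome_size_bp))
    return total_bp, ratio


def mean_length_bp(total_bp: int, n_variants: int) -> int:
    """Average CNV length as printed in summary tables (nearest bp)."""
    if n_variants <= 0:
        raise ValueError("n_variants must be positive")
    q = Decimal(total_bp) / Decimal(n_variants)
    return int(q.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def call_set_summary(loci: Sequence[CNVLocus], genome_size_bp: int) -> Dict[str, object]:
    """One summary-table row: total/DEL/DUP counts, bp coverage, genome ratio."""
    dels = [l for l in loci if l.svtype == "DEL"]
    dups = [l for l in loci if l.svtype == "DUP"]
    total_bp, ratio = genome_summary(loci, genome_size_bp)
    del_bp, del_ratio = genome_summary(dels, genome_size_bp) if dels else (0, 0.0)
    dup_bp, dup_ratio = genome_summary(dups, genome_size_bp) if dups else (0, 0.0)
    return {
        "total": len(loci),
        "del": len(dels),
        "dup": len(dups),
        "total_bp": total_bp,
        "genome_ratio_percent": ratio,
        "del_bp": del_bp,
        "del_ratio_percent": del_ratio,
        "dup_bp": dup_bp,
        "dup_ratio_percent": dup_ratio,
        "mean_length_bp": mean_length_bp(total_bp, len(loci)) if loci else 0,
    }


def per_chromosome_counts(loci: Sequence[CNVLocus]) -> pd.DataFrame:
    """DEL/DUP counts per chromosome, genome-ordered; counts partition the set."""
    rows: Dict[str, Dict[str, int]] = {}
    for l in loci:
        row = rows.setdefault(l.chrom, {"DEL": 0, "DUP": 0})
        row[l.svtype] += 1
    out = pd.DataFrame(
        [
            {"chrom": c, "del": rows[c]["DEL"], "dup": rows[c]["DUP"], "total": rows[c]["DEL"] + rows[c]["DUP"]}
            for c in sorted(rows, key=chrom_sort_key)
        ],
        columns=["chrom", "del", "dup", "total"],
    )
    return out


def placement_gof_pvalue(loci: Sequence[CNVLocus], chromosome_lengths: Dict[str, int]) -> float:
    """Chi-square goodness of fit of per-chromosome counts to length-proportional expectation."""
    counts = per_chromosome_counts(loci)
    obs = [0] * len(chromosome_lengths)
    chroms = list(chromosome_lengths)
    idx = {c: i for i, c in enumerate(chroms)}
    for _, row in counts.iterrows():
        obs[idx[row["chrom"]]] = row["total"]
    lengths = [chromosome_lengths[c] for c in chroms]
    total = sum(obs)
    expected = [total * l / sum(lengths) for l in lengths]
    stat, p = stats.chisquare(obs, expected)
    return float(p)
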