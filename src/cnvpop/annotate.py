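"""Genomic annotation of CNVs against a gene model.

Each CNV is assigned exactly one of eleven categories by a fixed precedence:

    exonic > splicing > ncRNA > UTR5 (or UTR5;UTR3) > UTR3 > intronic
    > upstream / downstream / upstream;downstream > intergenic

"exonic" means >=1 bp overlap with coding sequence (the CDS portion of a
coding exon); "splicing" is a 2 bp window into each intron at exon
boundaries; "ncRNA" is any overlap with a non-coding transcript; flanks are
1 kb on each side, with upstream defined on the transcript's strand. These
windows follow the ANNOVAR-style conventions the category vocabulary comes
from. Overlap for annotation means any shared base — no reciprocal-fraction
requirement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .core import CNVLocus

logger = logging.getLogger(__name__)

FLANK_BP = 1000
SPLICE_BP = 2

#: The eleven annotation categories, in report order.
CATEGORIES = (
    "downstream",
    "upstream",
    "upstream;downstream",
    "exonic",
    "intronic",
    "intergenic",
    "ncRNA",
    "splicing",
    "UTR3",
    "UTR5",
    "UTR5;UTR3",
)

Interval = Tuple[int, int]  # 1-based inclusive


def _clip(ivs: List[Interval]) -> List[Interval]:
    return [(s, e) for s, e in ivs if e >= s]


@dataclass
class Transcript:
    """A transcript with exon structure; CDS span absent for ncRNA."""

    id: str
    gene: str
    chrom: str
    strand: str  # '+' | '-'
    start: int
    end: int
    exons: List[Interval]  # sorted, non-overlapping, 1-based inclusive
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    biotype: str = "coding"  # coding | ncRNA

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s < self.start or e > self.end or e < s:
                raise ValueError(f"exon ({s},{e}) outside transcript span of {self.id}")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"overlapping exons in {self.id}")
            prev_end = e
        if self.biotype == "coding" and (self.cds_start is None or self.cds_end is None):
            raise ValueError(f"coding transcript {self.id} lacks a CDS span")

    # ---- derived feature intervals (all 1-based inclusive) ----

    def introns(self) -> List[Interval]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return _clip(out)

    def cds_intervals(self) -> List[Interval]:
        if self.cds_start is None:
            return []
        return _clip(
            [(max(s, self.cds_start), min(e, self.cds_end)) for s, e in self.exons]
        )

    def utr5_intervals(self) -> List[Interval]:
        """Exonic sequence 5' of the CDS on the coding strand."""
        if self.cds_start is None:
            return []
        if self.strand == "+":
            return _clip([(s, min(e, self.cds_start - 1)) for s, e in self.exons])
        return _clip([(max(s, self.cds_end + 1), e) for s, e in self.exons])

    def utr3_intervals(self) -> List[Interval]:
        if self.cds_start is None:
            return []
        if self.strand == "+":
            return _clip([(max(s, self.cds_end + 1), e) for s, e in self.exons])
        return _clip([(s, min(e, self.cds_start - 1)) for s, e in self.exons])

    def splice_windows(self, width: int = SPLICE_BP) -> List[Interval]:
        """``width`` bp into each intron at both of its exon boundaries."""
        out = []
        for s, e in self.introns():
            out.append((s, min(s + width - 1, e)))
            out.append((max(e - width + 1, s), e))
        return _clip(out)

    def upstream_flank(self, flank: int = FLANK_BP) -> Interval:
        if self.strand == "+":
            return (max(1, self.start - flank), self.start - 1)
        return (self.end + 1, self.end + flank)

    def downstream_flank(self, flank: int = FLANK_BP) -> Interval:
        if self.strand == "+":
            return (self.end + 1, self.end + flank)
        return (max(1, self.start - flank), self.start - 1)


class GeneModel:
    """Indexed collection of transcripts supporting interval queries."""

    def __init__(self, transcripts: Sequence[Transcript]):
        self.transcripts: List[Transcript] = list(transcripts)
        self._trees: Dict[str, IntervalTree] = {}
        for tx in self.transcripts:
            tree = self._trees.setdefault(tx.chrom, IntervalTree())
            # index the span plus the flank so one query catches flank-only hits
            tree.addi(tx.start - FLANK_BP, tx.end + FLANK_BP + 1, tx)

    def __len__(self) -> int:
        return len(self.transcripts)

    @property
    def genes(self) -> List[str]:
        seen: List[str] = []
        for tx in self.transcripts:
            if tx.gene not in seen:
                seen.append(tx.gene)
        return seen

    def candidates(self, locus: CNVLocus) -> List[Transcript]:
        tree = self._trees.get(locus.chrom)
        if tree is None:
            return []
        hits = tree.overlap(locus.start, locus.end + 1)
        return sorted((h.data for h in hits), key=lambda t: (t.start, t.id))


def _overlaps(locus: CNVLocus, iv: Interval) -> bool:
    return locus.start <= iv[1] and locus.end >= iv[0]


def classify_cnv(
    locus: CNVLocus,
    model: GeneModel,
    flank: int = FLANK_BP,
    splice_bp: int = SPLICE_BP,
) -> str:
    """Assign exactly one annotation category to a CNV."""
    if locus.chrom not in model._trees:
        logger.debug("chromosome %s absent from gene model; %s -> intergenic", locus.chrom, locus.id)
    txs = model.candidates(locus)

    hit_cds = hit_splice = hit_nc = hit_u5 = hit_u3 = hit_intron = False
    hit_up = hit_down = False
    for tx in txs:
        if tx.biotype == "ncRNA":
            if _overlaps(locus, (tx.start, tx.end)):
                hit_nc = True
        else:
            if any(_overlaps(locus, iv) for iv in tx.cds_intervals()):
                hit_cds = True
            if any(_overlaps(locus, iv) for iv in tx.splice_windows(splice_bp)):
                hit_splice = True
            if any(_overlaps(locus, iv) for iv in tx.utr5_intervals()):
                hit_u5 = True
            if any(_overlaps(locus, iv) for iv in tx.utr3_intervals()):
                hit_u3 = True
            if any(_overlaps(locus, iv) for iv in tx.introns()):
                hit_intron = True
        if _overlaps(locus, tx.upstream_flank(flank)):
            hit_up = True
        if _overlaps(locus, tx.downstream_flank(flank)):
            hit_down = True

    if hit_cds:
        return "exonic"
    if hit_splice:
        return "splicing"
    if hit_nc:
        return "ncRNA"
    if hit_u5 and hit_u3:
        return "UTR5;UTR3"
    if hit_u5:
        return "UTR5"
    if hit_u3:
        return "UTR3"
    if hit_intron:
        return "intronic"
    if hit_up and hit_down:
        return "upstream;downstream"
    if hit_up:
        return "upstream"
    if hit_down:
        return "downstream"
    return "intergenic"


def percent(count: int, total: int, decimals: int = 2) -> float:
    """Percentage rounded half-up to the printed precision."""
    if total == 0:
        return 0.0
    q = Decimal(100 * count) / Decimal(total)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


@dataclass
class AnnotationSummary:
    counts: Dict[str, int]
    percentages: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.counts.values())
        if not self.percentages:
            self.percentages = {c: percent(self.counts.get(c, 0), total) for c in CATEGORIES}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(CATEGORIES),
                "count": [self.counts.get(c, 0) for c in CATEGORIES],
                "percent": [self.percentages[c] for c in CATEGORIES],
            }
        )


def summarize_annotation(
    loci: Sequence[CNVLocus], model: GeneModel, flank: int = FLANK_BP
) -> AnnotationSummary:
    """Category counts and percentages over a CNV set (a partition of it)."""
    counts = {c: 0 for c in CATEGORIES}
    for locus in loci:
        counts[classify_cnv(locus, model, flank=flank)] += 1
    return AnnotationSummary(counts=counts)


def annotation_table(loci: Sequence[CNVLocus], model: GeneModel, flank: int = FLANK_BP) -> pd.DataFrame:
    """Per-locus annotation: id, category, overlapped gene names."""
    rows = []
    for locus in loci:
        cat = classify_cnv(locus, model, flank=flank)
        genes = sorted(
            {
                tx.gene
                for tx in model.candidates(locus)
                if locus.start <= tx.end + flank and locus.end >= tx.start - flank
            }
        )
        rows.append({"id": locus.id, "category": cat, "genes": ";".join(genes)})
    return pd.DataFrame(rows, columns=["id", "category", "genes"])


# ---------------------------------------------------------------------------
# Gene-model I/O: GFF3 (via gffutils) and BED12
# ---------------------------------------------------------------------------

def write_gff3(model: GeneModel, path) -> None:
    """Serialize the gene model as GFF3 (gene/mRNA|ncRNA/exon/CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in sorted(model.transcripts, key=lambda t: (t.chrom, t.start, t.id)):
            fh.write(
                f"{tx.chrom}\ttoy\tgene\t{tx.start}\t{tx.end}\t.\t{tx.strand}\t.\t"
                f"ID=gene:{tx.gene};Name={tx.gene}\n"
            )
            ftype = "mRNA" if tx.biotype == "coding" else "ncRNA"
            fh.write(
                f"{tx.chrom}\ttoy\t{ftype}\t{tx.start}\t{tx.end}\t.\t{tx.strand}\t.\t"
                f"ID=tx:{tx.id};Parent=gene:{tx.gene}\n"
            )
            for k, (s, e) in enumerate(tx.exons, 1):
                fh.write(
                    f"{tx.chrom}\ttoy\texon\t{s}\t{e}\t.\t{tx.strand}\t.\t"
                    f"ID=exon:{tx.id}.{k};Parent=tx:{tx.id}\n"
                )
            for s, e in tx.cds_intervals():
                fh.write(
                    f"{tx.chrom}\ttoy\tCDS\t{s}\t{e}\t.\t{tx.strand}\t0\t"
                    f"ID=cds:{tx.id};Parent=tx:{tx.id}\n"
                )


def read_gff3(path) -> GeneModel:
    """Parse a GFF3 gene model (gene/mRNA-or-ncRNA/exon/CDS) via gffutils.

    Uses a single streaming pass (``gffutils.DataIterator``), grouping exon
    and CDS features under their transcript by the Parent attribute.
    """
    import gffutils

    tx_feats: Dict[str, object] = {}
    gene_of: Dict[str, str] = {}
    exons: Dict[str, List[Interval]] = {}
    cds: Dict[str, List[Interval]] = {}
    for f in gffutils.DataIterator(str(path)):
        fid = f.attributes.get("ID", [None])[0]
        parents = f.attributes.get("Parent", [None])
        if f.featuretype in ("mRNA", "ncRNA", "transcript"):
            tx_feats[fid] = f
            gene_of[fid] = parents[0] or fid
        elif f.featuretype == "exon":
            for p in parents:
                exons.setdefault(p, []).append((f.start, f.end))
        elif f.featuretype == "CDS":
            for p in parents:
                cds.setdefault(p, []).append((f.start, f.end))
    transcripts: List[Transcript] = []
    for fid, f in tx_feats.items():
        ex = sorted(exons.get(fid, [])) or [(f.start, f.end)]
        cd = sorted(cds.get(fid, []))
        transcripts.append(
            Transcript(
                id=fid.split(":")[-1],
                gene=gene_of[fid].split(":")[-1],
                chrom=f.seqid,
                strand=f.strand if f.strand in ("+", "-") else "+",
                start=f.start,
                end=f.end,
                exons=ex,
                cds_start=cd[0][0] if cd else None,
                cds_end=cd[-1][1] if cd else None,
                biotype="ncRNA" if (f.featuretype == "ncRNA" or not cd) else "coding",
            )
        )
    return GeneModel(transcripts)


def read_bed12(path) -> GeneModel:
    """Parse a BED12 gene model; thickStart == thickEnd marks a non-coding entry."""
    transcripts: List[Transcript] = []
    for line in _bed_lines(path):
        parts = line.split("\t")
        if len(parts) < 12:
            raise ValueError(f"BED12 requires 12 columns, got {len(parts)}")
        chrom, cstart, cend, name, _score, strand = parts[:6]
        thick_start, thick_end = int(parts[6]), int(parts[7])
        n_blocks = int(parts[9])
        sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
        starts = [int(x) for x in parts[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise ValueError("BED12 block count mismatch")
        start0 = int(cstart)
        exons = [(start0 + s + 1, start0 + s + sz) for s, sz in zip(starts, sizes)]
        coding = thick_end > thick_start
        transcripts.append(
            Transcript(
                id=name,
                gene=name,
                chrom=chrom,
                strand=strand if strand in ("+", "-") else "+",
                start=int(cstart) + 1,
                end=int(cend),
                exons=exons,
                cds_start=thick_start + 1 if coding else None,
                cds_end=thick_end if coding else None,
                biotype="coding" if coding else "ncRNA",
            )
        )
    return GeneModel(transcripts)


def _bed_lines(path):
    from pathlib import Path

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith(("#", "track", "browser")):
            yield line
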