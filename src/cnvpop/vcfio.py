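"""CNV call-set I/O (VCF 4.2 with symbolic alleles) and allele-frequency math.

Reading and writing go through pysam; the in-memory product is a
:class:`~cnvpop.core.GenotypeMatrix`. Frequencies are plain alternate-allele
frequencies computed from diploid dosages, and the spectrum is the ten-bin
histogram ([0,0.1), ..., [0.9,1.0]) used to summarise a call set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pysam

from .core import (
    MISSING,
    CNVLocus,
    GenotypeMatrix,
    chrom_sort_key,
    is_autosome,
)

logger = logging.getLogger(__name__)

N_SPECTRUM_BINS = 10


@dataclass
class FrequencySpectrum:
    """Counts of loci in ten equal allele-frequency bins for one population."""

    bins: np.ndarray  # length 10
    population: str

    def __post_init__(self):
        self.bins = np.asarray(self.bins, dtype=int)
        if self.bins.shape != (N_SPECTRUM_BINS,):
            raise ValueError("spectrum must have exactly 10 bins")

    @property
    def total(self) -> int:
        return int(self.bins.sum())


def read_panel(path) -> Dict[str, str]:
    """Read a sample<TAB>population map (no header, '#' comments allowed)."""
    panel: Dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed panel line: {line!r}")
        panel[parts[0]] = parts[1]
    return panel


def write_panel(panel: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, pop in panel.items():
            fh.write(f"{sample}\t{pop}\n")


def _record_locus(rec) -> Optional[CNVLocus]:
    """Extract a CNVLocus from a VCF record, or None if it is not a DEL/DUP.

    Symbolic SV records use the padding convention: POS is the base before
    the event and END (pysam's ``rec.stop``, derived by htslib from END or
    SVLEN) is its last base, so the variant occupies POS+1..END inclusive.
    """
    svtype = rec.info.get("SVTYPE")
    if svtype is None and rec.alts:
        alt = rec.alts[0]
        if alt.startswith("<") and alt.endswith(">"):
            svtype = alt.strip("<>")
    if svtype not in ("DEL", "DUP"):
        return None
    start = rec.pos + 1
    end = rec.stop
    if end < start:
        raise ValueError("END precedes POS (or END/SVLEN missing)")
    return CNVLocus(rec.chrom, start, end, svtype, rec.id or f"{svtype}_{rec.chrom}_{start}")


def read_cnv_vcf(path, panel_path) -> GenotypeMatrix:
    """Load a symbolic-allele CNV VCF and a population panel into a matrix.

    Records on non-autosome contigs, with non-DEL/DUP SVTYPE (INV, BND, ...),
    shorter than the 50 bp CNV floor, or with END < POS are dropped; each
    class of exclusion is counted and logged.
    """
    panel = read_panel(panel_path)
    loci: List[CNVLocus] = []
    columns: List[np.ndarray] = []
    n_nonautosome = n_othertype = n_rejected = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        unmapped = [s for s in samples if s not in panel]
        if unmapped:
            raise ValueError(f"VCF samples missing from panel: {unmapped}")
        for rec in vf:
            if not is_autosome(rec.chrom):
                n_nonautosome += 1
                continue
            try:
                locus = _record_locus(rec)
            except ValueError as exc:
                logger.warning("rejecting record %s: %s", rec.id or rec.pos, exc)
                n_rejected += 1
                continue
            if locus is None:
                n_othertype += 1
                continue
            col = np.empty(len(samples), dtype=np.int16)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    col[i] = MISSING
                else:
                    col[i] = sum(1 for a in gt if a and a > 0)
            loci.append(locus)
            columns.append(col)
    if n_nonautosome:
        logger.info("dropped %d records on non-autosome contigs", n_nonautosome)
    if n_othertype:
        logger.info("skipped %d non-DEL/DUP records", n_othertype)
    if n_rejected:
        logger.info("rejected %d malformed records", n_rejected)
    dosage = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0), dtype=np.int16)
    )
    return GenotypeMatrix(loci=loci, samples=samples, panel=panel, dosage=dosage)


def write_cnv_vcf(matrix: GenotypeMatrix, path, contig_lengths: Optional[Dict[str, int]] = None) -> None:
    """Write the matrix as a VCF 4.2 with symbolic ALT and SVTYPE/END/SVLEN.

    SVLEN is signed: negative for deletions, positive for duplications.
    Records are emitted sorted by (chrom, start).
    """
    header = pysam.VariantHeader()
    contigs: Dict[str, int] = dict(contig_lengths or {})
    for locus in matrix.loci:
        contigs[locus.chrom] = max(contigs.get(locus.chrom, 0), locus.end + 1)
    for chrom in sorted(contigs, key=chrom_sort_key):
        header.contigs.add(chrom, length=contigs[chrom])
    header.add_meta("ALT", items=[("ID", "DEL"), ("Description", "Deletion")])
    header.add_meta("ALT", items=[("ID", "DUP"), ("Description", "Duplication")])
    header.add_meta(
        "INFO", items=[("ID", "SVTYPE"), ("Number", "1"), ("Type", "String"), ("Description", "SV type")]
    )
    header.add_meta(
        "INFO",
        items=[("ID", "END"), ("Number", "1"), ("Type", "Integer"), ("Description", "End position (1-based inclusive)")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "SVLEN"), ("Number", "1"), ("Type", "Integer"), ("Description", "Signed SV length")],
    )
    header.add_meta(
        "FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")]
    )
    for s in matrix.samples:
        header.add_sample(s)

    order = sorted(range(matrix.n_loci), key=lambda j: matrix.loci[j].sort_key())
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j in order:
            locus = matrix.loci[j]
            if locus.start < 2:
                raise ValueError(
                    f"locus {locus.id} starts at base 1; symbolic SV records need a padding base"
                )
            rec = vf.new_record(
                contig=locus.chrom,
                start=locus.start - 2,  # POS = padding base before the event
                stop=locus.end,
                alleles=("N", f"<{locus.svtype}>"),
                id=locus.id or None,
            )
            rec.info["SVTYPE"] = locus.svtype
            rec.info["SVLEN"] = -locus.length if locus.svtype == "DEL" else locus.length
            for i, s in enumerate(matrix.samples):
                d = matrix.dosage[i, j]
                if d == MISSING:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = (0, 1) if d == 1 else ((1, 1) if d == 2 else (0, 0))
            vf.write(rec)


def allele_frequencies(matrix: GenotypeMatrix, population: str) -> np.ndarray:
    """Per-locus alternate-allele frequency within one population.

    frequency = sum(dosage) / (2 * non-missing sample count); NaN where every
    genotype in the population is missing.
    """
    idx = matrix.sample_indices(population)
    sub = matrix.dosage[idx, :].astype(float)
    obs = sub != MISSING
    n_obs = obs.sum(axis=0)
    alt = np.where(obs, sub, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)
    return freq


def frequency_spectrum(freqs: Sequence[float], population: str = "") -> FrequencySpectrum:
    """Histogram of allele frequencies into the ten canonical bins.

    Bins are half-open [a, a+0.1) except the last, which is [0.9, 1.0] closed.
    NaN frequencies (no data in the population) are excluded.
    """
    arr = np.asarray(freqs, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    idx = np.minimum((arr * N_SPECTRUM_BINS).astype(int), N_SPECTRUM_BINS - 1)
    bins = np.bincount(idx, minlength=N_SPECTRUM_BINS)
    return FrequencySpectrum(bins=bins, population=population)


def write_bed(loci: Sequence[CNVLocus], path) -> None:
    """Write loci as BED (0-based half-open), sorted in genome order."""
    with open(path, "w") as fh:
        for locus in sorted(loci, key=lambda l: l.sort_key()):
            fh.write(f"{locus.chrom}\t{locus.start - 1}\t{locus.end}\t{locus.id}\t{locus.svtype}\n")
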