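"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive throughout the in-memory model (the VCF
convention); conversion to 0-based half-open happens only at BED output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

SVTYPES = ("DEL", "DUP")

#: Minimum CNV length in bp. Calls below this are not copy-number variants
#: by the usual definition (structural variants range from 50 bp to several Mb).
MIN_CNV_LENGTH = 50

#: Sentinel for a missing diploid dosage in the genotype matrix.
MISSING = -1

_AUTOSOME_RE = re.compile(r"^(chr)?([1-9][0-9]*)$")


def is_autosome(chrom: str) -> bool:
    return _AUTOSOME_RE.match(chrom) is not None


def chrom_sort_key(chrom: str):
    """Natural chromosome ordering: numbered autosomes first, then others."""
    m = _AUTOSOME_RE.match(chrom)
    if m:
        return (0, int(m.group(2)), "")
    return (1, 0, chrom)


@dataclass(frozen=True)
class CNVLocus:
    """One copy-number variant call (deletion or duplication)."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    svtype: str  # DEL | DUP
    id: str = ""

    def __post_init__(self):
        if self.svtype not in SVTYPES:
            raise ValueError(f"svtype must be one of {SVTYPES}, got {self.svtype!r}")
        if self.end < self.start:
            raise ValueError(f"end < start for locus {self.id!r} ({self.chrom}:{self.start}-{self.end})")
        if self.length < MIN_CNV_LENGTH:
            raise ValueError(
                f"CNV length {self.length} bp below the {MIN_CNV_LENGTH} bp floor "
                f"({self.chrom}:{self.start}-{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def sort_key(self):
        return (*chrom_sort_key(self.chrom), self.start, self.end, self.svtype)


@dataclass
class GenotypeMatrix:
    """Samples x loci diploid alternate-allele dosages with a population panel.

    ``dosage[i, j]`` counts the symbolic alternate allele (0, 1 or 2) carried
    by sample ``i`` at locus ``j``; ``MISSING`` (-1) marks an uncalled genotype.
    Both deletions and duplications are treated as biallelic presence/absence
    of the variant allele, matching how biallelic SV genotypers emit them.
    """

    loci: List[CNVLocus]
    samples: List[str]
    panel: Dict[str, str]
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        if self.dosage.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        valid = np.isin(self.dosage, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.dosage[~valid])
            raise ValueError(f"dosages must be in {{0,1,2,missing}}; found {bad}")
        missing_panel = [s for s in self.samples if s not in self.panel]
        if missing_panel:
            raise ValueError(f"samples without a population label: {missing_panel}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> List[str]:
        seen: List[str] = []
        for s in self.samples:
            p = self.panel[s]
            if p not in seen:
                seen.append(p)
        return seen

    def sample_indices(self, population: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.panel[s] == population]
        if not idx:
            raise ValueError(f"unknown population label {population!r}")
        return np.asarray(idx)


def sort_loci_with_index(loci: Sequence[CNVLocus]):
    """Return (sorted loci, argsort index) in (chrom, start) genome order."""
    order = sorted(range(len(loci)), key=lambda i: loci[i].sort_key())
    return [loci[i] for i in order], np.asarray(order, dtype=int)
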