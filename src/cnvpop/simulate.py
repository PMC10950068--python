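"""Two-population CNV genotype simulator with known divergence.

The generative model is Balding-Nichols: each locus has an ancestral
alternate-allele frequency p drawn from a beta distribution, and each
population's frequency is drawn from Beta(p(1-F)/F, (1-p)(1-F)/F), whose
mean is p and whose variance is F*p*(1-p). F is the divergence (fixation
index) parameter, so the per-locus differentiation statistic downstream has
a known generating value. A small configurable fraction of loci receive a
much larger F ("selected" loci), planting outliers that a top-tail scan
should recover. Diploid genotypes are binomial(2, population frequency).

Loci are placed uniformly (length-weighted across chromosomes) without
same-type overlap, with log-normal lengths; defaults emulate a domestic-pig
versus wild-boar contrast: 18 autosomes, 18+19 samples, a deletion-rich
call set (~4% duplications), a low-frequency-skewed ancestral spectrum, and
a median CNV length near 280 bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .annotate import GeneModel, Transcript
from .core import MISSING, MIN_CNV_LENGTH, CNVLocus, GenotypeMatrix
from .fst import fst_from_frequencies

#: Sus scrofa 11.1 autosome lengths (bp), chromosomes 1-18.
PIG_AUTOSOME_LENGTHS: Dict[str, int] = {
    "1": 274330532, "2": 151935994, "3": 132848913, "4": 130910915,
    "5": 104526007, "6": 170843587, "7": 121844099, "8": 138966237,
    "9": 139512083, "10": 69359453, "11": 79169978, "12": 61602749,
    "13": 208334590, "14": 141755446, "15": 140412725, "16": 79944280,
    "17": 63494081, "18": 55982971,
}

#: Genome size used for coverage ratios; the assembly total including
#: unplaced scaffolds and sex chromosomes (~2.5 Gb), not just the autosomes.
PIG_GENOME_SIZE = 2_506_000_000

_MAX_CNV_LENGTH = 5_000_000  # "50 bp to several Mb"


@dataclass
class SimulationConfig:
    """Parameters of the two-population Balding-Nichols CNV simulation."""

    n_loci: int = 16408
    n_samples_pop1: int = 18
    n_samples_pop2: int = 19
    F_background: float = 0.05
    F_selected: float = 0.8
    selected_fraction: float = 0.01
    dup_fraction: float = 0.042
    ancestral_freq_dist: Tuple[float, float] = (0.5, 2.0)
    length_dist: Tuple[float, float] = (math.log(282.0), 2.23)  # log-scale mu, sigma
    n_chromosomes: int = 18
    chromosome_lengths: Dict[str, int] = field(
        default_factory=lambda: dict(PIG_AUTOSOME_LENGTHS)
    )
    missing_rate: float = 0.0
    pop1_name: str = "pop1"
    pop2_name: str = "pop2"
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_loci, (int, np.integer)) and self.n_loci > 0):
            raise ValueError("n_loci must be a positive integer")
        if self.n_samples_pop1 <= 0 or self.n_samples_pop2 <= 0:
            raise ValueError("sample counts must be positive")
        for name in ("F_background", "F_selected"):
            f = getattr(self, name)
            if not (np.isfinite(f) and 0.0 < f < 1.0):
                raise ValueError(f"{name} must be finite and in (0, 1), got {f}")
        if not (0.0 <= self.selected_fraction < 1.0):
            raise ValueError("selected_fraction must be in [0, 1)")
        if self.selected_fraction > 0 and self.F_selected < self.F_background:
            raise ValueError("F_selected must be >= F_background when selected loci exist")
        if not (0.0 <= self.dup_fraction <= 1.0):
            raise ValueError("dup_fraction must be in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        a, b = self.ancestral_freq_dist
        if a <= 0 or b <= 0:
            raise ValueError("ancestral beta shape parameters must be positive")
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ValueError("chromosome_lengths must list n_chromosomes entries")
        if any(l <= 0 for l in self.chromosome_lengths.values()):
            raise ValueError("chromosome lengths must be positive")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SimulatedTruth:
    """Per-locus ground truth of one simulation run."""

    ids: List[str]
    ancestral_freq: np.ndarray
    pop1_freq: np.ndarray
    pop2_freq: np.ndarray
    selected: np.ndarray  # bool
    fst_realized: np.ndarray  # from the drawn frequencies, not genotypes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "ancestral_freq": self.ancestral_freq,
                "pop1_freq": self.pop1_freq,
                "pop2_freq": self.pop2_freq,
                "selected": self.selected.astype(int),
                "fst_realized": self.fst_realized,
            }
        )


def _place_loci(
    rng: np.random.Generator, config: SimulationConfig, svtypes: np.ndarray
) -> List[Tuple[str, int, int]]:
    """Uniform length-weighted placement without same-type overlap."""
    chroms = list(config.chromosome_lengths)
    lengths = np.array([config.chromosome_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    mu, sigma = config.length_dist
    sizes = np.clip(
        np.round(rng.lognormal(mu, sigma, size=len(svtypes))).astype(np.int64),
        MIN_CNV_LENGTH,
        _MAX_CNV_LENGTH,
    )
    occupied: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    placements: List[Optional[Tuple[str, int, int]]] = [None] * len(svtypes)
    import bisect

    # Largest first: a multi-Mb locus needs a gap its own size, which only
    # exists reliably while the genome is still nearly empty.
    for k in sorted(range(len(svtypes)), key=lambda i: -int(sizes[i])):
        size, svtype = int(sizes[k]), svtypes[k]
        placed = False
        for _ in range(200):
            ci = rng.choice(len(chroms), p=probs)
            chrom = chroms[ci]
            # start >= 2 so a VCF padding base always exists before the event
            limit = config.chromosome_lengths[chrom] - size + 1
            if limit < 2:
                continue
            start = int(rng.integers(2, limit + 1))
            end = start + size - 1
            key = (chrom, svtype)
            ivs = occupied.setdefault(key, [])
            i = bisect.bisect_left(ivs, (start, end))
            if i > 0 and ivs[i - 1][1] >= start:
                continue
            if i < len(ivs) and ivs[i][0] <= end:
                continue
            ivs.insert(i, (start, end))
            placements[k] = (chrom, start, end)
            placed = True
            break
        if not placed:
            raise ValueError(
                "could not place a locus without same-type overlap; "
                "genome too small for the requested locus count/lengths"
            )
    return placements


def simulate_populations(
    config: SimulationConfig,
) -> Tuple[List[CNVLocus], GenotypeMatrix, SimulatedTruth]:
    """Draw a two-population CNV genotype data set with known divergence.

    Returns the locus list (genome-sorted), the genotype matrix over
    n_samples_pop1 + n_samples_pop2 diploid samples, and the per-locus truth
    table (ancestral and drawn population frequencies, selected flags, and
    the Fst realized by the drawn frequencies). Deterministic given the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_loci

    n_selected = int(round(config.selected_fraction * n))
    selected = np.zeros(n, dtype=bool)
    if n_selected:
        selected[rng.choice(n, size=n_selected, replace=False)] = True

    a, b = config.ancestral_freq_dist
    p_anc = np.clip(rng.beta(a, b, size=n), 1e-4, 1.0 - 1e-4)
    F = np.where(selected, config.F_selected, config.F_background)
    scale = (1.0 - F) / F
    p1 = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)
    p2 = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)

    n1, n2 = config.n_samples_pop1, config.n_samples_pop2
    g1 = rng.binomial(2, p1[None, :], size=(n1, n))
    g2 = rng.binomial(2, p2[None, :], size=(n2, n))
    dosage = np.vstack([g1, g2]).astype(np.int16)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = MISSING

    n_dup = int(round(config.dup_fraction * n))
    svtypes = np.array(["DEL"] * n, dtype=object)
    if n_dup:
        svtypes[rng.choice(n, size=n_dup, replace=False)] = "DUP"

    placements = _place_loci(rng, config, svtypes)
    loci = [
        CNVLocus(chrom, start, end, svtype)
        for (chrom, start, end), svtype in zip(placements, svtypes)
    ]
    order = sorted(range(n), key=lambda i: loci[i].sort_key())
    order = np.asarray(order)
    width = len(str(n))
    loci = [
        CNVLocus(l.chrom, l.start, l.end, l.svtype, id=f"CNV_{k + 1:0{width}d}")
        for k, l in enumerate(loci[i] for i in order)
    ]
    p_anc, p1, p2, selected = p_anc[order], p1[order], p2[order], selected[order]
    dosage = dosage[:, order]

    samples = [f"{config.pop1_name}_{i + 1:03d}" for i in range(n1)] + [
        f"{config.pop2_name}_{i + 1:03d}" for i in range(n2)
    ]
    panel = {s: (config.pop1_name if i < n1 else config.pop2_name) for i, s in enumerate(samples)}
    matrix = GenotypeMatrix(loci=loci, samples=samples, panel=panel, dosage=dosage)

    fst_real = fst_from_frequencies(p1, p2)
    truth = SimulatedTruth(
        ids=[l.id for l in loci],
        ancestral_freq=p_anc,
        pop1_freq=p1,
        pop2_freq=p2,
        selected=selected,
        fst_realized=fst_real,
    )
    return loci, matrix, truth


def write_truth_table(truth: SimulatedTruth, path) -> None:
    """Write the per-locus ground truth as TSV (header + one row per locus)."""
    truth.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_truth_table(path) -> SimulatedTruth:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    return SimulatedTruth(
        ids=df["id"].tolist() if len(df) else [],
        ancestral_freq=df["ancestral_freq"].to_numpy(float),
        pop1_freq=df["pop1_freq"].to_numpy(float),
        pop2_freq=df["pop2_freq"].to_numpy(float),
        selected=df["selected"].to_numpy(int).astype(bool),
        fst_realized=df["fst_realized"].to_numpy(float),
    )


def generate_toy_gene_model(
    chromosome_lengths: Dict[str, int],
    density: float = 0.35,
    seed: int = 0,
    mean_transcript_length: float = 20_000.0,
    mean_exons: int = 4,
    coding_fraction: float = 0.8,
) -> GeneModel:
    """Random non-overlapping gene model for annotation tests.

    Coding transcripts carry UTR5/CDS/UTR3 structure; the remainder are
    ncRNA. ``density`` is the target fraction of the genome covered by
    transcript spans; the default approximates the genic fraction of a
    mammalian genome. Deterministic given the seed.
    """
    import bisect

    if not (0.0 <= density < 0.5):
        raise ValueError("density must be in [0, 0.5) to keep placement feasible")
    rng = np.random.default_rng(seed)
    transcripts: List[Transcript] = []
    tx_index = 0
    for chrom, clen in chromosome_lengths.items():
        target_bp = int(density * clen)
        occupied: List[Tuple[int, int]] = []
        covered = 0
        attempts = 0
        max_attempts = max(10_000, 20 * target_bp // int(mean_transcript_length))
        while covered < target_bp and attempts < max_attempts:
            attempts += 1
            span = int(np.clip(rng.exponential(mean_transcript_length), 1_000, clen // 2))
            start = int(rng.integers(1, max(2, clen - span)))
            end = start + span - 1
            # transcripts kept >= 2 kb apart so 1 kb flanks never abut a neighbor
            i = bisect.bisect_left(occupied, (start - 2_000, 0))
            if i > 0 and occupied[i - 1][1] >= start - 2_000:
                continue
            if i < len(occupied) and occupied[i][0] <= end + 2_000:
                continue
            n_exons = max(2, int(rng.poisson(mean_exons)))
            cuts = np.sort(rng.choice(np.arange(1, span - 1), size=min(2 * n_exons - 2, span - 2), replace=False))
            bounds = np.concatenate([[0], cuts, [span]])
            exons = []
            for k in range(0, len(bounds) - 1, 2):
                exons.append((start + int(bounds[k]), start + int(bounds[k + 1]) - 1))
            exons = [(s, e) for s, e in exons if e >= s]
            exons[0] = (start, exons[0][1])
            exons[-1] = (exons[-1][0], end)
            strand = "+" if rng.random() < 0.5 else "-"
            tx_index += 1
            biotype = "coding" if rng.random() < coding_fraction else "ncRNA"
            cds_start = cds_end = None
            if biotype == "coding":
                # CDS runs from inside the first exon to inside the last exon;
                # the leftover terminal-exon sequence forms the two UTRs.
                fs, fe = exons[0]
                ls, le = exons[-1]
                utr_a = int(rng.integers(1, fe - fs + 1)) if fe > fs else 0
                utr_b = int(rng.integers(1, le - ls + 1)) if le > ls else 0
                cds_start = min(fs + utr_a, fe)
                cds_end = max(le - utr_b, ls)
                if cds_end < cds_start:
                    cds_start, cds_end = fs, le
            transcripts.append(
                Transcript(
                    id=f"tx{tx_index:04d}",
                    gene=f"gene{tx_index:04d}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    biotype=biotype,
                )
            )
            occupied.insert(i, (start, end))
            covered += span
        if target_bp > 0 and covered < target_bp * 0.2 and attempts >= 10_000:
            raise ValueError(f"requested gene density {density} infeasible on {chrom}")
    return GeneModel(transcripts)
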