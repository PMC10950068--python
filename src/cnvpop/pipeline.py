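"""End-to-end orchestration of the CNV population-genomics workflow.

``run_all`` drives the full simulation-backed pipeline: generate a
two-population genotype set, derive per-population call sets, merge them,
annotate the merged loci against a gene model, compute population structure
(PCA + NJ tree), run the Fst selection scan with empirical top-tail
thresholding, overlap selected loci with genes, and (optionally) test the
gene list for term over-representation. Every stage writes a plain-text
artifact and the run summary JSON records the headline counts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from . import annotate as ann
from . import fst as fstmod
from .enrich import TermEntry, TermMap, enrich as compute_enrichment, enrichment_table
from . import merge as mrg
from . import popstruct as ps
from . import vcfio
from .core import CNVLocus, GenotypeMatrix
from .simulate import (
    PIG_GENOME_SIZE,
    SimulationConfig,
    generate_toy_gene_model,
    simulate_populations,
    write_truth_table,
)

logger = logging.getLogger(__name__)


def population_call_sets(matrix: GenotypeMatrix) -> Dict[str, List[CNVLocus]]:
    """Per-population call sets: loci carried by at least one sample."""
    out: Dict[str, List[CNVLocus]] = {}
    for pop in matrix.populations:
        freqs = vcfio.allele_frequencies(matrix, pop)
        out[pop] = [l for l, f in zip(matrix.loci, freqs) if np.isfinite(f) and f > 0]
    return out


def generate_toy_term_map(genes: List[str], n_terms: int = 25, mean_term_size: int = 12,
                          seed: int = 0) -> TermMap:
    """Random gene→term map over a gene universe, for exercising enrichment."""
    rng = np.random.default_rng(seed)
    genes = list(genes)
    terms: Dict[str, TermEntry] = {}
    categories = ("biological process", "cellular component", "molecular function", "pathway")
    for t in range(n_terms):
        size = max(2, int(rng.poisson(mean_term_size)))
        size = min(size, len(genes))
        members = set(rng.choice(genes, size=size, replace=False).tolist())
        tid = f"TERM:{t + 1:04d}"
        terms[tid] = TermEntry(tid, f"toy term {t + 1}", categories[t % len(categories)], members)
    return TermMap(terms=terms, universe=set(genes))


def write_term_map(term_map: TermMap, path) -> None:
    with open(path, "w") as fh:
        for term in term_map.terms.values():
            for g in sorted(term.genes):
                fh.write(f"{g}\t{term.term_id}\t{term.name}\t{term.category}\n")


def run_all(
    config: SimulationConfig,
    outdir,
    merge_threshold: float = 0.5,
    top_fraction: float = 0.01,
    flank: int = 1000,
    gene_density: float = 0.35,
    genome_size_bp: int = PIG_GENOME_SIZE,
    n_components: int = 2,
) -> Dict:
    """Run the full simulated workflow into ``outdir``; return the run summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("simulating %d loci over %d+%d samples (seed %d)",
                config.n_loci, config.n_samples_pop1, config.n_samples_pop2, config.seed)
    loci, matrix, truth = simulate_populations(config)
    vcfio.write_cnv_vcf(matrix, outdir / "genotypes.vcf", contig_lengths=config.chromosome_lengths)
    vcfio.write_panel(matrix.panel, outdir / "panel.tsv")
    write_truth_table(truth, outdir / "truth.tsv")

    model = generate_toy_gene_model(config.chromosome_lengths, density=gene_density,
                                    seed=config.seed + 1)
    ann.write_gff3(model, outdir / "genes.gff3")

    pops = matrix.populations
    pop_a, pop_b = pops[0], pops[1]
    call_sets = population_call_sets(matrix)
    merged = mrg.merge_call_sets(call_sets[pop_a], call_sets[pop_b],
                                 reciprocal_overlap=merge_threshold, labels=(pop_a, pop_b))
    shared, uniq_a, uniq_b, shared_pct, uniq_a_pct = mrg.sharing_counts(merged)
    vcfio.write_bed(merged.loci, outdir / "merged.bed")
    summary_rows = {
        pop_a: mrg.call_set_summary(call_sets[pop_a], genome_size_bp),
        pop_b: mrg.call_set_summary(call_sets[pop_b], genome_size_bp),
        "merged": mrg.call_set_summary(merged.loci, genome_size_bp),
    }
    mrg.per_chromosome_counts(merged.loci).to_csv(outdir / "per_chromosome.tsv", sep="\t", index=False)

    spectra = {}
    for pop in (pop_a, pop_b):
        freqs = vcfio.allele_frequencies(matrix, pop)
        spec = vcfio.frequency_spectrum(freqs[np.isfinite(freqs) & (freqs > 0)], population=pop)
        spectra[pop] = spec.bins.tolist()
    pd.DataFrame(spectra).to_csv(outdir / "frequency_spectrum.tsv", sep="\t", index=False)

    annot = ann.summarize_annotation(merged.loci, model, flank=flank)
    annot.to_frame().to_csv(outdir / "annotation_summary.tsv", sep="\t", index=False)
    ann.annotation_table(merged.loci, model, flank=flank).to_csv(
        outdir / "annotation.tsv", sep="\t", index=False
    )

    pcares = ps.pca(matrix, k=n_components)
    pd.DataFrame(
        pcares.coordinates,
        index=pcares.samples,
        columns=[f"PC{i + 1}" for i in range(pcares.coordinates.shape[1])],
    ).to_csv(outdir / "pca.tsv", sep="\t")
    dm = ps.allele_sharing_distance(matrix)
    tree = ps.neighbor_joining(dm)
    (outdir / "nj_tree.nwk").write_text(tree.to_newick() + "\n")

    records = fstmod.scan(matrix, pop_a, pop_b)
    result = fstmod.select_top(records, top_fraction=top_fraction)
    fstmod.manhattan_table(result).to_csv(outdir / "fst_scan.tsv", sep="\t", index=False)
    genes = fstmod.selected_gene_overlap(result, model, matrix.loci, flank=flank)
    (outdir / "selected_genes.txt").write_text("".join(g + "\n" for g in genes))

    enrichment_rows = []
    if genes:
        term_map = generate_toy_term_map(model.genes, seed=config.seed + 2)
        write_term_map(term_map, outdir / "term_map.tsv")
        in_universe = [g for g in genes if g in term_map.universe]
        if in_universe:
            enrichment_rows = compute_enrichment(in_universe, term_map)
            enrichment_table(enrichment_rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    summary = {
        "seed": config.seed,
        "populations": [pop_a, pop_b],
        "n_samples": {pop_a: config.n_samples_pop1, pop_b: config.n_samples_pop2},
        "call_set_summary": summary_rows,
        "sharing": {
            "shared": shared,
            f"unique_{pop_a}": uniq_a,
            f"unique_{pop_b}": uniq_b,
            "shared_percent": shared_pct,
            f"unique_{pop_a}_percent": uniq_a_pct,
            "merged_total": len(merged.loci),
        },
        "annotation_counts": annot.counts,
        "annotation_percent": annot.percentages,
        "annotation_total": annot.total,
        "pca_explained": pcares.explained.tolist(),
        "fst": {
            "n_defined": result.n_defined,
            "top_fraction": top_fraction,
            "n_selected": len(result.selected_ids),
            "threshold": result.threshold,
        },
        "selected_genes": genes,
        "n_selected_genes": len(genes),
        "n_enriched_terms": len(enrichment_rows),
    }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
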