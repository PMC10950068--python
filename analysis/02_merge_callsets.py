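#!/usr/bin/env python
"""Characterize and merge the per-population CNV call sets.

Derives each population's call set (loci carried by at least one sample),
merges them at 50% reciprocal overlap, and writes the summary-table row per
call set (counts, bp coverage, genome ratio, mean length), the Venn-style
sharing counts, per-chromosome DEL/DUP counts, and the ten-bin allele
frequency spectra.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cnvpop import (
    PIG_GENOME_SIZE,
    allele_frequencies,
    call_set_summary,
    frequency_spectrum,
    merge_call_sets,
    per_chromosome_counts,
    population_call_sets,
    read_cnv_vcf,
    sharing_counts,
    write_bed,
)

BASE = Path(__file__).resolve().parents[1] / "results"


def main():
    matrix = read_cnv_vcf(BASE / "sim" / "genotypes.vcf", BASE / "sim" / "panel.tsv")
    out = BASE / "merge"
    out.mkdir(parents=True, exist_ok=True)

    pop_a, pop_b = matrix.populations
    call_sets = population_call_sets(matrix)
    merged = merge_call_sets(call_sets[pop_a], call_sets[pop_b],
                             reciprocal_overlap=0.5, labels=(pop_a, pop_b))
    shared, uniq_a, uniq_b, shared_pct, uniq_a_pct = sharing_counts(merged)

    rows = []
    for name, loci in [(pop_a, call_sets[pop_a]), (pop_b, call_sets[pop_b]),
                       ("merged", merged.loci)]:
        rows.append({"call_set": name} | call_set_summary(loci, PIG_GENOME_SIZE))
    table1 = pd.DataFrame(rows)
    table1.to_csv(out / "call_set_summary.tsv", sep="\t", index=False)
    per_chromosome_counts(merged.loci).to_csv(out / "per_chromosome.tsv", sep="\t", index=False)
    write_bed(merged.loci, out / "merged.bed")

    spectra = {}
    for pop in (pop_a, pop_b):
        f = allele_frequencies(matrix, pop)
        spectra[pop] = frequency_spectrum(f[np.isfinite(f) & (f > 0)], population=pop).bins
    pd.DataFrame(spectra, index=[f"{i / 10:.1f}-{(i + 1) / 10:.1f}" for i in range(10)]).to_csv(
        out / "frequency_spectrum.tsv", sep="\t"
    )

    sharing = {"shared": shared, f"unique_{pop_a}": uniq_a, f"unique_{pop_b}": uniq_b,
               "shared_percent": shared_pct, f"unique_{pop_a}_percent": uniq_a_pct,
               "merged_total": len(merged.loci)}
    (out / "sharing.json").write_text(json.dumps(sharing, indent=2))

    print(table1.to_string(index=False))
    print(f"\nmerged union: {len(merged.loci)} loci; {shared} shared ({shared_pct}%), "
          f"{uniq_a} unique to {pop_a} ({uniq_a_pct}%), {uniq_b} unique to {pop_b}")
    for pop in (pop_a, pop_b):
        frac = spectra[pop][0] / spectra[pop].sum() * 100
        print(f"{pop}: lowest-frequency bin (0-0.1) holds {frac:.1f}% of segregating loci")


if __name__ == "__main__":
    main()
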