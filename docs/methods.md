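# Methods

## Scope and data model

The pipeline starts at CNV *call sets*: biallelic deletion/duplication loci
with diploid genotypes, as emitted by an SV caller plus a population
genotyper. Read mapping and calling are upstream of this package. Internally
a call set is a `GenotypeMatrix`: samples × loci alternate-allele dosages in
{0, 1, 2, missing} with a sample→population panel. Coordinates are 1-based
inclusive (VCF convention); BED output converts to 0-based half-open. Both
DELs and DUPs are treated as biallelic presence/absence of the variant allele
— multi-allelic copy states are out of scope. Loci shorter than 50 bp are
rejected (below that size a variant is an indel, not a CNV), and only
autosomal records are analyzed; non-autosome, non-DEL/DUP and malformed
records are dropped with logged counts.

VCF records use the symbolic-allele padding convention: POS is the base
before the event, END its last base, SVLEN signed (negative for deletions).
This is the only representation that round-trips through htslib, which
derives END from POS + |SVLEN| for symbolic alleles.

## The synthetic cohort

The generative model is Balding–Nichols. Per locus, an ancestral alternate
frequency `p ~ Beta(a, b)` (clipped to [1e-4, 1−1e-4] to keep the
subpopulation betas proper); each population draws its frequency from
`Beta(p(1−F)/F, (1−p)(1−F)/F)`, which has mean `p` and variance `F·p(1−p)`,
so `F` is the locus's divergence parameter; diploid genotypes are
`Binomial(2, frequency)`. All draws flow from a single `numpy` generator
seeded by one integer, so a run is bit-reproducible.

Defaults — these are the study conditions the tests run under:

| parameter | default | rationale |
|---|---|---|
| `n_loci` | 16,408 | a merged two-population CNV call set of realistic size |
| `n_samples_pop1/2` | 18 / 19 | a conservation-farm breed panel vs a wild panel |
| `F_background` | 0.05 | modest neutral differentiation between a breed and its wild relative |
| `F_selected` / `selected_fraction` | 0.8 / 0.01 | a 1% minority of strongly differentiated loci for the scan to find |
| `dup_fraction` | 0.042 | short-read CNV call sets are deletion-rich (~4% duplications) |
| `ancestral_freq_dist` | Beta(0.5, 2) | low-frequency-skewed spectrum: the 0–0.1 bin is modal, as in real CNV spectra |
| `length_dist` | lognormal(ln 282, 2.23) | median ≈ 280 bp with a heavy tail to several Mb, matching observed CNV length distributions; clipped to [50 bp, 5 Mb] |
| chromosomes | 18 pig autosomes (Sscrofa11.1 lengths) | length-proportional placement |
| `missing_rate` | 0 | injectable for testing missing-data handling |

Loci are placed uniformly (chromosome chosen in proportion to its length)
with no same-type overlap. Placement runs largest-first and is then restored
to locus order: a multi-Mb locus can only find an overlap-free gap while the
genome is nearly empty; the procedure stays deterministic given the seed.

The per-locus truth table records ancestral and drawn population
frequencies, the selected flag, and the F<sub>ST</sub> realized by the drawn
frequencies.

What the generator does *not* emulate: linkage disequilibrium between loci
(loci are independent), genotyping error and caller-specific biases,
multi-allelic copy states, and mutation/recombination dynamics. Passing
tests therefore demonstrate correctness of the statistics under a clean
biallelic model, not robustness to caller artifacts.

A companion toy gene model places non-overlapping multi-exon transcripts
(80% coding with UTR5/CDS/UTR3 on terminal exons, 20% ncRNA) covering a
configurable genome fraction; the default 0.35 approximates the genic
fraction of a mammalian genome. Its exon/intron geometry is not calibrated
to real exon-size distributions, so annotation *proportions* from simulated
runs are not comparable to real annotation tables — only the classification
logic is.

## Merging and summaries

Two calls are equivalent when they share chromosome and type and each covers
≥ 50% of the other (reciprocal overlap), the community convention for SV
identity. Clusters are built single-linkage, left-to-right over start-sorted
loci, so the procedure is deterministic, order-independent between the two
input sets, and idempotent; the merged record spans the union interval and
keeps full provenance (every input call belongs to exactly one merged
record). Coverage totals union-collapse same-type overlaps before summing so
no base is counted twice; genome ratios and sharing percentages are rounded
half-up to two decimals, the convention of printed summary tables. The genome
size used for ratios defaults to 2.506 Gb (full assembly including unplaced
scaffolds, not just the autosome sum).

## Annotation

Each CNV receives exactly one of eleven categories by fixed precedence:
exonic (≥1 bp overlap with CDS) > splicing (2 bp into an intron at an exon
boundary) > ncRNA (any overlap with a non-coding transcript) > UTR5;UTR3 /
UTR5 / UTR3 > intronic > upstream / downstream / upstream;downstream (1 kb
flanks, strand-aware) > intergenic. Windows follow ANNOVAR-style
conventions; overlap means any shared base, with no reciprocal-fraction
requirement. The categories partition the input by construction, and the
implementation is checked against a per-base brute-force enumeration oracle
on random instances. Queries run on an interval tree over transcript spans
(± flank).

## Population structure

PCA follows the smartpca convention: drop loci with pooled frequency 0 or 1
or zero variance, impute missing dosages to twice the pooled frequency,
normalize by `sqrt(p̂(1−p̂))`, and eigendecompose the sample covariance.
Coordinates are eigenvectors scaled by the root eigenvalue; each component's
sign is fixed by making its largest-magnitude locus loading positive, so
results are fully deterministic.

The tree is Saitou–Nei neighbor joining over the allele-sharing distance
`d(i,j) = mean |dosage_i − dosage_j| / 2` (loci called in both samples),
a model-free metric in [0, 1] for biallelic markers. Pair selection uses the
Q-criterion with lexicographic tie-breaking on the active pair; negative limb
lengths are clamped to zero with the deficit moved to the sister limb; the
final three nodes are resolved by the three-point formulas. NJ is exact on
additive matrices, which the tests exploit: random binary trees →
patristic distances → NJ must return the same bipartition set.

## Selection scan

F<sub>ST</sub> uses unweighted means for `Hs` and `p̄` (with two equal-weight
demes this is Nei's G<sub>ST</sub>); loci with `Ht = 0` are *undefined*,
never zero, and are excluded from the tail denominator. The candidate set is
the top `⌊f·N⌋` of defined values (default `f = 0.01`; the floor convention
reproduces 164 from 16,408). Ties at the cut are broken by genomic position
and cut exactly. No multiple-testing correction applies — this is an
empirical-outlier scan, not a test. Candidate genes are those whose
transcript span ± 1 kb intersects a selected locus, reported once each in
genome order.

**Recall definition.** Scan recall on synthetic data is measured over
planted loci *observable in the call set* (defined F<sub>ST</sub>). Under
`F = 0.8` with a low-frequency-skewed ancestral spectrum, roughly two thirds
of planted loci drift to absence in both populations; such loci never appear
in any real call set (a call set contains only observed variants), so
counting them against the scan would measure allele loss, not scan quality.
Observable-locus recall is 0.56–0.89 across seeds at the default
configuration; recall over all planted loci is structurally capped near 0.3
by allele loss alone.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
`P(X ≥ k)` for each term with at least one query hit, with
Benjamini–Hochberg adjustment across the tested terms; the background
universe defaults to the genes of the supplied term map and can be widened
(e.g. to all genes of the gene model). Terms come from a local
gene→term TSV; no live ontology database is queried. Note that omitting
zero-overlap terms from the BH family (only terms with `k ≥ 1` are tested)
is the standard behavior of over-representation tools but makes the
correction slightly anti-conservative when the term map is large and the
query small.

## Numerical and design notes

- `Fst = (Ht−Hs)/Ht` is evaluated directly; its identity with
  `(p1−p2)²/(4p̄q̄)` is exact in algebra and agrees to ~1e-15 in floating
  point away from `Ht → 0`; within ~1e-9 of the degenerate point the
  subtraction loses digits, which is why undefined loci are flagged rather
  than computed.
- Mean per-locus F̂<sub>ST</sub> under Balding–Nichols is *not* the
  parameter `F`: finite-sample frequency noise (here 2n = 100 alleles per
  population) and the ratio form both bias the per-locus estimator upward
  relative to the ratio-of-expectations `F/(2−F)`. Parameter recovery is
  therefore validated against an independently coded Monte-Carlo oracle of
  the same model, not against `F` itself; monotonicity in `F` is checked
  separately.
- Percentages that mirror printed tables use decimal half-up rounding, not
  banker's rounding.
- The test and acceptance problem sizes (2,000-locus × 100-sample
  simulations, 20 Monte-Carlo replicates, 200 random trees of ≤ 12 taxa,
  100 annotation instances) were chosen as the smallest sizes at which the
  Monte-Carlo standard errors are well below the effects being checked.

## Known limitations

- The merge stage is pairwise (two call sets); k-way merging is expressible
  by folding but provenance then reflects fold order at sub-threshold
  chains.
- Left-to-right single-linkage can split a chain when an intervening long
  call fails the reciprocal test against an earlier cluster; this matches
  the stated deterministic rule but is not a global clustering.
- The allele-sharing distance ignores missingness patterns beyond pairwise
  deletion; samples sharing no called locus are an error, not an imputation.
- `upstream;downstream` requires flanks of two transcripts (or both flanks
  of one) to be hit without any higher-precedence feature; with the toy
  model's 2 kb inter-transcript spacing such loci are rare but present.
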