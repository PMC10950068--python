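import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvpop import (
    CNVLocus,
    GeneModel,
    GenotypeMatrix,
    SimulationConfig,
    Transcript,
    fst_from_frequencies,
    locus_fst,
    manhattan_table,
    scan,
    select_top,
    selected_gene_overlap,
    simulate_populations,
)
from cnvpop.fst import FstRecord, ScanResult


def closed_form(p1, p2):
    pbar = (p1 + p2) / 2
    denom = 4 * pbar * (1 - pbar)
    return (p1 - p2) ** 2 / denom if denom > 0 else float("nan")


def test_identical_populations_have_zero_fst():
    r = locus_fst(0.5, 0.5)
    assert (r.hs, r.ht, r.fst) == (0.5, 0.5, 0.0)


def test_alternately_fixed_populations_have_fst_one():
    r = locus_fst(0.0, 1.0)
    assert r.hs == 0.0 and r.ht == 0.5 and r.fst == 1.0


def test_hand_computed_example():
    r = locus_fst(0.2, 0.8)
    assert r.hs == pytest.approx(0.32)
    assert r.ht == pytest.approx(0.5)
    assert r.fst == pytest.approx(0.36)
    assert r.fst == pytest.approx(closed_form(0.2, 0.8))


def test_undefined_fst_is_flagged_not_zero():
    r = locus_fst(0.0, 0.0)
    assert math.isnan(r.fst) and not r.defined
    r = locus_fst(1.0, 1.0)
    assert math.isnan(r.fst)


@pytest.mark.parametrize("bad", [-0.1, 1.1, float("nan")])
def test_out_of_range_frequency_rejected(bad):
    with pytest.raises(ValueError):
        locus_fst(bad, 0.5)


def test_vectorised_path_rejects_out_of_range_but_passes_nan_through():
    with pytest.raises(ValueError):
        fst_from_frequencies([0.2, -0.1], [0.3, 0.3])
    # NaN means "no data in that population": undefined, not an error
    out = fst_from_frequencies([0.2, float("nan")], [0.8, 0.3])
    assert out[0] == pytest.approx(0.36) and math.isnan(out[1])


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    p1=st.floats(min_value=0, max_value=1, allow_nan=False),
    p2=st.floats(min_value=0, max_value=1, allow_nan=False),
)
def test_fst_properties_bounds_symmetry_closed_form(p1, p2):
    r = locus_fst(p1, p2)
    if r.defined:
        assert -1e-12 <= r.fst <= 1 + 1e-12
        assert r.fst == pytest.approx(closed_form(p1, p2), abs=1e-10)
    # symmetry and allele-relabeling invariance (skip the relabel check in
    # the Ht -> 0 cancellation zone, where float subtraction loses all digits)
    r_swap = locus_fst(p2, p1)
    if r.defined:
        assert r_swap.defined and r_swap.fst == pytest.approx(r.fst, abs=1e-10)
    else:
        assert not r_swap.defined
    r_flip = locus_fst(1 - p1, 1 - p2)
    if r.defined and r.ht > 1e-9 and r_flip.defined and r_flip.ht > 1e-9:
        assert r_flip.fst == pytest.approx(r.fst, abs=1e-8)


# ---- scan ----


def small_two_pop_matrix(columns):
    """columns: list of (popA dosages, popB dosages) per locus."""
    nA = len(columns[0][0])
    nB = len(columns[0][1])
    samples = [f"a{i}" for i in range(nA)] + [f"b{i}" for i in range(nB)]
    panel = {s: ("A" if s.startswith("a") else "B") for s in samples}
    dosage = np.array([[col[0][i] for col in columns] for i in range(nA)]
                      + [[col[1][i] for col in columns] for i in range(nB)], dtype=np.int16)
    loci = [CNVLocus("1", 1000 * (j + 1), 1000 * (j + 1) + 99, "DEL", f"l{j}") for j in range(len(columns))]
    return GenotypeMatrix(loci=loci, samples=samples, panel=panel, dosage=dosage)


def test_scan_on_monomorphic_identical_matrix():
    m = small_two_pop_matrix([
        ([0, 0], [0, 0]),      # absent everywhere -> undefined
        ([2, 2], [2, 2]),      # fixed everywhere -> undefined
        ([1, 1], [1, 1]),      # same frequency -> 0
    ])
    recs = scan(m, "A", "B")
    assert not recs[0].defined and not recs[1].defined
    assert recs[2].defined and recs[2].fst == pytest.approx(0.0)


def test_scan_requires_distinct_populations(small_matrix):
    with pytest.raises(ValueError):
        scan(small_matrix, "popA", "popA")


def test_label_permutation_collapses_mean_fst(rng):
    cfg = SimulationConfig(
        n_loci=1000, n_samples_pop1=20, n_samples_pop2=20, F_background=0.4,
        selected_fraction=0.0, seed=13,
        n_chromosomes=1, chromosome_lengths={"1": 20_000_000},
    )
    _, m, _ = simulate_populations(cfg)
    real = np.nanmean([r.fst for r in scan(m, "pop1", "pop2")])
    perm = rng.permutation(m.n_samples)
    shuffled_panel = {s: m.panel[m.samples[perm[i]]] for i, s in enumerate(m.samples)}
    m_perm = GenotypeMatrix(loci=m.loci, samples=m.samples, panel=shuffled_panel, dosage=m.dosage)
    permuted = np.nanmean([r.fst for r in scan(m_perm, "pop1", "pop2")])
    assert permuted < real / 3


# ---- top-tail selection ----


def records_from_values(values):
    return [
        FstRecord(id=f"r{i}", p1=0.0, p2=0.0, hs=0.0, ht=1.0, fst=v, chrom="1", start=i)
        for i, v in enumerate(values)
    ]


def test_select_top_floor_convention():
    rng = np.random.default_rng(0)
    vals = rng.permutation(np.linspace(0.001, 0.999, 100))
    res = select_top(records_from_values(vals), 0.01)
    assert len(res.selected_ids) == 1
    assert res.threshold == pytest.approx(vals.max())
    res250 = select_top(records_from_values(rng.permutation(np.linspace(0.001, 0.999, 250))), 0.01)
    assert len(res250.selected_ids) == 2  # floor(2.5)


def test_select_top_excludes_undefined_from_denominator():
    vals = [0.9, 0.8, float("nan"), 0.7] + [0.1] * 196
    res = select_top(records_from_values(vals), 0.01)
    assert res.n_defined == 199
    assert len(res.selected_ids) == 1  # floor(1.99)
    assert res.selected_ids == ["r0"]


def test_select_top_tie_break_is_positional_and_deterministic():
    vals = [0.5, 0.5, 0.5, 0.5] + [0.1] * 196
    res = select_top(records_from_values(vals), 0.01)
    assert res.selected_ids == ["r0", "r1"]  # ties cut by (chrom, start)


def test_threshold_consistency_on_unselected_remainder():
    rng = np.random.default_rng(1)
    recs = records_from_values(rng.uniform(0, 1, 500))
    res = select_top(recs, 0.01)
    rest = [r for r in recs if r.id not in set(res.selected_ids)]
    res2 = select_top(rest, 0.01)
    assert all(r.fst <= res.threshold for r in res2.records if r.defined)


def test_select_top_input_validation():
    with pytest.raises(ValueError):
        select_top(records_from_values([float("nan")]), 0.01)
    with pytest.raises(ValueError):
        select_top(records_from_values([0.5]), 1.5)


def test_paper_scale_arithmetic_164_of_16408():
    rng = np.random.default_rng(2)
    vals = rng.uniform(0, 1, 16408)  # distinct with probability 1
    res = select_top(records_from_values(vals), 0.01)
    assert len(res.selected_ids) == 164


# ---- gene overlap of selected loci ----


def one_gene_model():
    tx = Transcript(id="t", gene="G1", chrom="1", strand="+", start=5000, end=9000,
                    exons=[(5000, 9000)], cds_start=5100, cds_end=8900)
    return GeneModel([tx])


def test_gene_overlap_empty_single_and_unique():
    model = one_gene_model()
    loci = [
        CNVLocus("1", 100, 400, "DEL", "far"),
        CNVLocus("1", 6000, 6200, "DEL", "inside1"),
        CNVLocus("1", 7000, 7200, "DEL", "inside2"),
    ]
    mk = lambda ids: ScanResult(records=[], selected_ids=ids, threshold=0.5,
                                top_fraction=0.01, n_defined=3)
    assert selected_gene_overlap(mk(["far"]), model, loci) == []
    assert selected_gene_overlap(mk(["inside1"]), model, loci) == ["G1"]
    assert selected_gene_overlap(mk(["inside1", "inside2"]), model, loci) == ["G1"]
    # 1 kb flank counts as overlap
    flank_locus = [CNVLocus("1", 4200, 4400, "DEL", "nearby")]
    assert selected_gene_overlap(mk(["nearby"]), model, flank_locus) == ["G1"]


def test_manhattan_table_rows_and_order():
    recs = [
        FstRecord("b", 0.1, 0.9, 0, 1, 0.5, chrom="2", start=100, end=200),
        FstRecord("a", 0.1, 0.9, 0, 1, 0.9, chrom="1", start=500, end=700),
        FstRecord("c", 0.0, 0.0, 0, 0, float("nan"), chrom="1", start=900, end=950),
    ]
    res = ScanResult(records=recs, selected_ids=["a"], threshold=0.9, top_fraction=0.01, n_defined=2)
    tab = manhattan_table(res)
    assert len(tab) == 2  # undefined excluded
    assert tab.iloc[0]["id"] == "a" and tab.iloc[1]["id"] == "b"  # genome order
    assert bool(tab.iloc[0]["selected"]) and not bool(tab.iloc[1]["selected"])


def test_scan_recall_of_planted_outliers_in_call_set():
    cfg = SimulationConfig(n_loci=16408, seed=7)  # F_sel=0.8, F_bg=0.05, 1% planted
    _, m, truth = simulate_populations(cfg)
    recs = scan(m, "pop1", "pop2")
    res = select_top(recs, 0.01)
    defined = {r.id for r in recs if r.defined}
    planted = set(np.array(truth.ids)[truth.selected])
    observable = planted & defined  # loci present in the observed call set
    recall = len(set(res.selected_ids) & observable) / len(observable)
    assert recall >= 0.5
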