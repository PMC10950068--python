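import numpy as np
import pytest

from cnvpop import (
    CNVLocus,
    DistanceMatrix,
    GenotypeMatrix,
    SimulationConfig,
    allele_sharing_distance,
    neighbor_joining,
    pca,
    random_binary_tree,
    same_topology,
    simulate_populations,
    tree_distance_matrix,
)


def matrix_from_dosage(dosage, panel=None):
    dosage = np.asarray(dosage, dtype=np.int16)
    n, L = dosage.shape
    samples = [f"s{i}" for i in range(n)]
    loci = [CNVLocus("1", 1000 * (j + 1), 1000 * (j + 1) + 99, "DEL", f"l{j}") for j in range(L)]
    panel = panel or {s: "P" for s in samples}
    return GenotypeMatrix(loci=loci, samples=samples, panel=panel, dosage=dosage)


# ---- allele-sharing distance ----


def test_distance_identical_and_opposite_samples():
    m = matrix_from_dosage([[0, 0, 0], [0, 0, 0], [2, 2, 2]])
    d = allele_sharing_distance(m)
    assert d.values[0, 1] == 0.0
    assert d.values[0, 2] == 1.0


def test_distance_hand_computation():
    m = matrix_from_dosage([[0, 1, 2], [2, 1, 0]])
    d = allele_sharing_distance(m)
    assert d.values[0, 1] == pytest.approx(2 / 3)


def test_distance_requires_shared_called_loci():
    m = matrix_from_dosage([[0, -1], [-1, 2]])
    with pytest.raises(ValueError, match="share no called locus"):
        allele_sharing_distance(m)


def test_distance_metric_properties_on_simulated_data():
    cfg = SimulationConfig(
        n_loci=300, n_samples_pop1=6, n_samples_pop2=6, seed=4,
        n_chromosomes=1, chromosome_lengths={"1": 5_000_000},
    )
    _, m, _ = simulate_populations(cfg)
    d = allele_sharing_distance(m).values
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0)
    n = d.shape[0]
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(values=np.array([[0, 1], [2, 0]]), labels=["a", "b"])
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(values=np.array([[1.0, 1], [1, 0]]), labels=["a", "b"])


# ---- neighbor joining ----


def test_nj_recovers_four_taxon_tree_exactly():
    # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
    labels = ["A", "B", "C", "D"]
    D = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        dtype=float,
    )
    tree = neighbor_joining(DistanceMatrix(values=D, labels=labels))
    # topology: AB | CD
    assert frozenset({"A", "B"}) in tree.bipartitions()
    # branch lengths reproduce the input distances exactly
    paths = tree.leaf_path_lengths()
    idx = {l: i for i, l in enumerate(labels)}
    for (a, b), d in paths.items():
        assert d == pytest.approx(D[idx[a], idx[b]], abs=1e-9)


def test_nj_three_taxa_closed_form():
    D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    tree = neighbor_joining(DistanceMatrix(values=D, labels=["a", "b", "c"]))
    center = tree.root
    limbs = {tree.leaf_names[n]: w for n, w in tree.adjacency[center].items()}
    assert limbs == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})
    assert tree.internal_degrees() == [3]


def test_nj_rejects_small_or_invalid_input():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(values=np.zeros((2, 2)), labels=["a", "b"]))


@pytest.mark.parametrize("seed", range(10))
def test_nj_recovers_random_additive_topologies(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    truth = random_binary_tree([f"T{i}" for i in range(n)], rng)
    recovered = neighbor_joining(tree_distance_matrix(truth))
    assert same_topology(truth, recovered)
    assert all(deg == 3 for deg in recovered.internal_degrees())
    assert sorted(recovered.leaves()) == sorted(truth.leaves())


def test_nj_branch_lengths_non_negative_on_noisy_input(rng):
    n = 8
    base = tree_distance_matrix(random_binary_tree([f"T{i}" for i in range(n)], rng))
    noise = rng.uniform(0, 0.4, size=(n, n))
    noisy = base.values + (noise + noise.T) / 2
    np.fill_diagonal(noisy, 0.0)
    tree = neighbor_joining(DistanceMatrix(values=noisy, labels=base.labels))
    for node, nbrs in tree.adjacency.items():
        for w in nbrs.values():
            assert w >= 0.0


def test_newick_round_trip_through_dendropy():
    dendropy = pytest.importorskip("dendropy")
    rng = np.random.default_rng(3)
    truth = random_binary_tree([f"T{i}" for i in range(9)], rng)
    recovered = neighbor_joining(tree_distance_matrix(truth))
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=truth.to_newick(), schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=recovered.to_newick(), schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
    assert rf == 0


def test_nj_agrees_with_skbio_on_random_matrix():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(5)
    truth = random_binary_tree([f"T{i}" for i in range(7)], rng)
    dm = tree_distance_matrix(truth)
    ours = neighbor_joining(dm)
    sk_dm = skbio.DistanceMatrix(dm.values, ids=dm.labels)
    sk_tree = skbio.tree.nj(sk_dm)
    sk_splits = set()
    all_leaves = frozenset(dm.labels)
    for node in sk_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            sk_splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    assert sk_splits == ours.bipartitions()


# ---- PCA ----


def test_pca_two_samples_single_locus():
    m = matrix_from_dosage([[0], [2]])
    res = pca(m, k=1)
    assert res.explained[0] == pytest.approx(1.0)
    assert res.coordinates[0, 0] != pytest.approx(res.coordinates[1, 0])


def test_pca_errors_on_monomorphic_matrix():
    m = matrix_from_dosage([[1, 2], [1, 2], [1, 2]])
    with pytest.raises(ValueError, match="no polymorphic locus"):
        pca(m)


def test_pca_truncates_k_with_warning():
    m = matrix_from_dosage([[0, 0], [2, 2], [1, 1]])
    with pytest.warns(UserWarning, match="truncating"):
        res = pca(m, k=5)
    assert res.coordinates.shape[1] <= 2


def test_pca_components_orthogonal_and_variance_sorted():
    cfg = SimulationConfig(
        n_loci=500, n_samples_pop1=12, n_samples_pop2=12, F_background=0.2, seed=6,
        n_chromosomes=1, chromosome_lengths={"1": 10_000_000},
    )
    _, m, _ = simulate_populations(cfg)
    res = pca(m, k=4)
    G = res.coordinates.T @ res.coordinates
    off = G - np.diag(np.diag(G))
    assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()
    assert all(np.diff(res.explained) <= 1e-12)
    assert np.all((res.explained >= 0) & (res.explained <= 1))


def test_pca_invariant_to_sample_order_up_to_sign(rng):
    cfg = SimulationConfig(
        n_loci=400, n_samples_pop1=8, n_samples_pop2=8, F_background=0.2, seed=7,
        n_chromosomes=1, chromosome_lengths={"1": 10_000_000},
    )
    _, m, _ = simulate_populations(cfg)
    res = pca(m, k=2)
    perm = rng.permutation(m.n_samples)
    m2 = GenotypeMatrix(
        loci=m.loci,
        samples=[m.samples[i] for i in perm],
        panel=m.panel,
        dosage=m.dosage[perm, :],
    )
    res2 = pca(m2, k=2)
    back = np.empty_like(res2.coordinates)
    back[perm, :] = res2.coordinates
    for j in range(2):
        agree = np.allclose(back[:, j], res.coordinates[:, j], atol=1e-8)
        flipped = np.allclose(back[:, j], -res.coordinates[:, j], atol=1e-8)
        assert agree or flipped


def test_pc1_sign_separates_divergent_populations():
    cfg = SimulationConfig(
        n_loci=2000, n_samples_pop1=50, n_samples_pop2=50, F_background=0.3,
        selected_fraction=0.0, seed=5,
    )
    _, m, _ = simulate_populations(cfg)
    res = pca(m, k=2)
    labels = np.array([m.panel[s] for s in m.samples])
    side = res.coordinates[:, 0] > 0
    mis = min((side != (labels == "pop1")).sum(), (side == (labels == "pop1")).sum())
    assert mis == 0


def test_nj_tree_longest_internal_edge_splits_populations():
    cfg = SimulationConfig(
        n_loci=1000, n_samples_pop1=10, n_samples_pop2=10, F_background=0.3,
        selected_fraction=0.0, seed=10,
        n_chromosomes=1, chromosome_lengths={"1": 20_000_000},
    )
    _, m, _ = simulate_populations(cfg)
    tree = neighbor_joining(allele_sharing_distance(m))
    # find the internal edge with the largest length and take its leaf split
    best = None
    for a, nbrs in tree.adjacency.items():
        for b, w in nbrs.items():
            if a in tree.leaf_names or b in tree.leaf_names or a > b:
                continue
            if best is None or w > best[0]:
                best = (w, a, b)
    _, a, b = best

    def side_leaves(node, parent):
        if node in tree.leaf_names:
            return {tree.leaf_names[node]}
        out = set()
        for nb in tree.adjacency[node]:
            if nb != parent:
                out |= side_leaves(nb, node)
        return out

    split = side_leaves(b, a)
    pops = {m.panel[s] for s in split}
    other = {m.panel[s] for s in set(m.samples) - split}
    assert len(pops) == 1 and len(other) == 1 and pops != other
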