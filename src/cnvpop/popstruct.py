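"""Population structure from CNV genotypes: PCA and a neighbor-joining tree.

PCA follows the smartpca convention: each locus is centered by twice its
pooled allele frequency and scaled by sqrt(p(1-p)); missing dosages are
imputed to the centered mean; monomorphic loci are dropped. Sample
coordinates are eigenvectors of the sample covariance matrix scaled by the
square root of their eigenvalues.

The tree is classic Saitou-Nei neighbor joining over the allele-sharing
distance d(i,j) = mean |dosage_i - dosage_j| / 2, a model-free metric in
[0,1] for biallelic markers. The result is an unrooted binary tree whose
internal nodes have degree three, serialized as Newick.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core import MISSING, GenotypeMatrix


@dataclass
class PcaResult:
    coordinates: np.ndarray  # samples x k
    explained: np.ndarray  # variance fractions, non-increasing
    samples: List[str]
    n_loci_used: int


def pca(matrix: GenotypeMatrix, k: int = 10) -> PcaResult:
    """Principal components of the genotype matrix (smartpca normalization)."""
    if matrix.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = matrix.dosage.astype(float)
    X[matrix.dosage == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p_hat = np.nanmean(X, axis=0) / 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        var = np.nanvar(X, axis=0)
    usable = np.isfinite(p_hat) & (p_hat > 0) & (p_hat < 1) & (var > 0)
    if not usable.any():
        raise ValueError("no polymorphic locus with data; PCA undefined")
    X = X[:, usable]
    p = p_hat[usable]
    X = np.where(np.isnan(X), 2 * p, X)
    Z = (X - 2 * p) / np.sqrt(p * (1 - p))
    n, L = Z.shape
    G = Z @ Z.T / L
    eigval, eigvec = np.linalg.eigh(G)
    eigval, eigvec = eigval[::-1], eigvec[:, ::-1]
    eigval = np.where(eigval > 1e-10 * max(eigval[0], 1.0), eigval, 0.0)
    rank = int((eigval > 0).sum())
    if k > rank:
        warnings.warn(f"k={k} exceeds usable rank {rank}; truncating", stacklevel=2)
        k = rank
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(k):
        loadings = Z.T @ eigvec[:, j]
        i = int(np.argmax(np.abs(loadings)))
        if loadings[i] < 0:
            coords[:, j] = -coords[:, j]
    explained = eigval[:k] / eigval.sum() if eigval.sum() > 0 else np.zeros(k)
    return PcaResult(
        coordinates=coords, explained=explained, samples=list(matrix.samples), n_loci_used=L
    )


@dataclass
class DistanceMatrix:
    values: np.ndarray
    labels: List[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")


def allele_sharing_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise mean |dosage difference| / 2 over loci non-missing in both."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = matrix.dosage.astype(float)
    obs = matrix.dosage != MISSING
    n = matrix.n_samples
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            if not both.any():
                raise ValueError(
                    f"samples {matrix.samples[i]} and {matrix.samples[j]} share no called locus"
                )
            D[i, j] = D[j, i] = np.abs(X[i, both] - X[j, both]).mean() / 2.0
    return DistanceMatrix(values=D, labels=list(matrix.samples))


# ---------------------------------------------------------------------------
# Unrooted trees: adjacency representation, Newick, bipartitions
# ---------------------------------------------------------------------------


@dataclass
class NjTree:
    """Unrooted tree: adjacency map node -> {neighbor: branch length}.

    Leaves are labelled; internal nodes have degree 3 (or 3+ at the
    serialization root). ``root`` is the internal node used for Newick output.
    """

    adjacency: Dict[int, Dict[int, float]]
    leaf_names: Dict[int, str]
    root: int

    def leaves(self) -> List[str]:
        return sorted(self.leaf_names.values())

    def internal_degrees(self) -> List[int]:
        return [
            len(nbrs) for node, nbrs in self.adjacency.items() if node not in self.leaf_names
        ]

    def to_newick(self) -> str:
        def rec(node: int, parent: Optional[int]) -> str:
            children = [n for n in self.adjacency[node] if n != parent]
            if not children:
                return self.leaf_names[node]
            inner = ",".join(
                f"{rec(c, node)}:{self.adjacency[node][c]:.10g}" for c in children
            )
            label = self.leaf_names.get(node, "")
            return f"({inner}){label}"

        return rec(self.root, None) + ";"

    def bipartitions(self) -> Set[FrozenSet[str]]:
        """Non-trivial leaf splits, one side per internal edge (canonical: the
        smaller/lexicographically-first side)."""
        all_leaves = frozenset(self.leaf_names.values())

        def collect(node: int, parent: int) -> FrozenSet[str]:
            if node in self.leaf_names:
                return frozenset([self.leaf_names[node]])
            out: Set[str] = set()
            for n in self.adjacency[node]:
                if n != parent:
                    out |= collect(n, node)
            return frozenset(out)

        splits: Set[FrozenSet[str]] = set()
        seen = set()
        for a in self.adjacency:
            for b in self.adjacency[a]:
                if (b, a) in seen:
                    continue
                seen.add((a, b))
                side = collect(b, a)
                other = all_leaves - side
                if len(side) < 2 or len(other) < 2:
                    continue
                canon = min(side, other, key=lambda s: (len(s), sorted(s)))
                splits.add(canon)
        return splits

    def leaf_path_lengths(self) -> Dict[Tuple[str, str], float]:
        """Pairwise patristic distances between leaves."""
        leaves = {n: name for n, name in self.leaf_names.items()}
        out: Dict[Tuple[str, str], float] = {}
        for start, sname in leaves.items():
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, w in self.adjacency[u].items():
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for other, oname in leaves.items():
                if oname > sname:
                    out[(sname, oname)] = dist[other]
        return out


def same_topology(t1: NjTree, t2: NjTree) -> bool:
    """True iff the two unrooted trees induce identical leaf bipartitions."""
    if t1.leaves() != t2.leaves():
        return False
    return t1.bipartitions() == t2.bipartitions()


def neighbor_joining(dist: DistanceMatrix) -> NjTree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair (i, j) minimizing
    Q(i,j) = (n-2) d(i,j) - r_i - r_j (ties broken by the lexicographically
    smallest active pair). Limb lengths use the standard formulas; a negative
    limb is clamped to zero and its deficit moved to the sister limb. The
    final three nodes are resolved by the three-point formulas.
    """
    n0 = len(dist.labels)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D: Dict[int, Dict[int, float]] = {}
    active: List[int] = list(range(n0))
    for i in active:
        D[i] = {j: float(dist.values[i, j]) for j in active if j != i}
    adjacency: Dict[int, Dict[int, float]] = {i: {} for i in active}
    leaf_names = {i: dist.labels[i] for i in active}
    next_id = n0

    def clamp_pair(li: float, lj: float) -> Tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        n = len(active)
        r = {i: sum(D[i][j] for j in active if j != i) for i in active}
        best = None
        best_q = math.inf
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * D[i][j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        dij = D[i][j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        u = next_id
        next_id += 1
        adjacency[u] = {i: li, j: lj}
        adjacency[i][u] = li
        adjacency[j][u] = lj
        D[u] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i][k] + D[j][k] - dij)
            D[u][k] = duk
            D[k][u] = duk
            del D[k][i], D[k][j]
        active = [k for k in active if k not in (i, j)] + [u]
        del D[i], D[j]

    a, b, c = active
    la = 0.5 * (D[a][b] + D[a][c] - D[b][c])
    lb = 0.5 * (D[a][b] + D[b][c] - D[a][c])
    lc = 0.5 * (D[a][c] + D[b][c] - D[a][b])
    center = next_id
    adjacency[center] = {}
    for node, length in ((a, la), (b, lb), (c, lc)):
        length = max(length, 0.0)
        adjacency[center][node] = length
        adjacency[node][center] = length
    return NjTree(adjacency=adjacency, leaf_names=leaf_names, root=center)


# ---------------------------------------------------------------------------
# Random additive trees (validation utilities)
# ---------------------------------------------------------------------------


def random_binary_tree(labels: Sequence[str], rng: np.random.Generator,
                       min_branch: float = 0.1, max_branch: float = 2.0) -> NjTree:
    """Random unrooted binary tree with branch lengths in [min_branch, max_branch]."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 leaves")
    adjacency: Dict[int, Dict[int, float]] = {}
    leaf_names: Dict[int, str] = {}

    def blen() -> float:
        return float(rng.uniform(min_branch, max_branch))

    # start from a 3-leaf star, then attach leaves onto random edges
    center = len(labels)
    adjacency[center] = {}
    for i in range(3):
        adjacency[i] = {center: blen()}
        adjacency[center][i] = adjacency[i][center]
        leaf_names[i] = labels[i]
    next_id = center + 1
    for i in range(3, len(labels)):
        edges = [(a, b) for a in adjacency for b in adjacency[a] if a < b]
        a, b = edges[int(rng.integers(len(edges)))]
        w = adjacency[a][b]
        split = float(rng.uniform(0.2, 0.8)) * w
        mid = next_id
        next_id += 1
        del adjacency[a][b], adjacency[b][a]
        adjacency[mid] = {a: split, b: w - split}
        adjacency[a][mid] = split
        adjacency[b][mid] = w - split
        adjacency[i] = {mid: blen()}
        adjacency[mid][i] = adjacency[i][mid]
        leaf_names[i] = labels[i]
    return NjTree(adjacency=adjacency, leaf_names=leaf_names, root=center)


def tree_distance_matrix(tree: NjTree) -> DistanceMatrix:
    """Additive (patristic) leaf distance matrix of a tree."""
    labels = tree.leaves()
    idx = {name: i for i, name in enumerate(labels)}
    D = np.zeros((len(labels), len(labels)))
    for (a, b), d in tree.leaf_path_lengths().items():
        D[idx[a], idx[b]] = D[idx[b], idx[a]] = d
    return DistanceMatrix(values=D, labels=labels)
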