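import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from cnvpop import CNVLocus, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """Hand-built matrix: 5 samples in two populations, 4 loci."""
    loci = [
        CNVLocus("1", 1001, 1300, "DEL", "d1"),
        CNVLocus("1", 5001, 5600, "DEL", "d2"),
        CNVLocus("2", 2001, 2100, "DUP", "u1"),
        CNVLocus("3", 100, 900, "DEL", "d3"),
    ]
    samples = ["a1", "a2", "a3", "b1", "b2"]
    panel = {"a1": "popA", "a2": "popA", "a3": "popA", "b1": "popB", "b2": "popB"}
    dosage = np.array(
        [
            [0, 2, 1, 0],
            [1, 2, 0, 0],
            [2, 1, 0, 0],
            [0, 0, 2, 2],
            [1, -1, 2, 2],
        ],
        dtype=np.int16,
    )
    return GenotypeMatrix(loci=loci, samples=samples, panel=panel, dosage=dosage)


def random_gene_instance(seed, chrom_len=200_000, n_loci=100):
    """Small random gene model + CNV set for oracle-equivalence checks."""
    from cnvpop import generate_toy_gene_model

    rng = np.random.default_rng(seed)
    model = generate_toy_gene_model(
        {"1": chrom_len},
        density=0.35,
        seed=seed,
        mean_transcript_length=6_000,
        mean_exons=3,
        coding_fraction=0.7,
    )
    loci = []
    for i in range(n_loci):
        length = int(rng.integers(50, 4_000))
        start = int(rng.integers(1, chrom_len - length))
        svtype = "DEL" if rng.random() < 0.9 else "DUP"
        loci.append(CNVLocus("1", start, start + length - 1, svtype, f"L{i}"))
    return model, loci
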