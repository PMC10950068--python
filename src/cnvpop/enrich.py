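"""Over-representation analysis of a gene list against a local gene→term map.

For each term with at least one query hit, the p-value is the upper-tail
hypergeometric probability P(X >= k) of drawing k or more of the term's K
genes in a query of size n from a universe of N genes, followed by
Benjamini-Hochberg adjustment across the tested terms. The term database is
a plain TSV supplied by the user; no live ontology access is involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class TermEntry:
    term_id: str
    name: str
    category: str
    genes: Set[str]


@dataclass
class TermMap:
    terms: Dict[str, TermEntry]
    universe: Set[str]

    def __post_init__(self):
        for t in self.terms.values():
            extra = t.genes - self.universe
            if extra:
                raise ValueError(f"term {t.term_id} contains genes outside the universe: {sorted(extra)[:5]}")


@dataclass
class EnrichmentRow:
    term_id: str
    name: str
    category: str
    k: int  # query genes in term
    n: int  # query size
    K: int  # term size
    N: int  # universe size
    p_value: float
    q_value: float
    genes: List[str] = field(default_factory=list)


def read_term_map(path, universe: Optional[Iterable[str]] = None) -> TermMap:
    """Read a gene→term TSV: gene, term_id, term_name[, category].

    The universe defaults to all genes appearing in the file; pass an explicit
    universe (e.g. all genes of the gene model) to widen the background.
    """
    terms: Dict[str, TermEntry] = {}
    genes_seen: Set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed term-map line: {line!r}")
        gene, term_id = parts[0], parts[1]
        name = parts[2] if len(parts) > 2 else term_id
        category = parts[3] if len(parts) > 3 else ""
        entry = terms.setdefault(term_id, TermEntry(term_id, name, category, set()))
        entry.genes.add(gene)
        genes_seen.add(gene)
    uni = set(universe) if universe is not None else genes_seen
    uni |= genes_seen
    return TermMap(terms=terms, universe=uni)


def enrich(genes: Iterable[str], term_map: TermMap) -> List[EnrichmentRow]:
    """Hypergeometric over-representation of the query against every term.

    Terms with zero query overlap are omitted. Rows are sorted by p ascending
    (ties by term id).
    """
    if not term_map.universe:
        raise ValueError("empty gene universe")
    query = set(genes)
    dropped = query - term_map.universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes absent from the universe were dropped", stacklevel=2
        )
        query -= dropped
    if not query:
        raise ValueError("empty query after restricting to the universe")
    N = len(term_map.universe)
    n = len(query)
    rows: List[EnrichmentRow] = []
    for term in term_map.terms.values():
        hit = query & term.genes
        k = len(hit)
        if k == 0:
            continue
        K = len(term.genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            EnrichmentRow(
                term_id=term.term_id,
                name=term.name,
                category=term.category,
                k=k,
                n=n,
                K=K,
                N=N,
                p_value=min(p, 1.0),
                q_value=float("nan"),
                genes=sorted(hit),
            )
        )
    if rows:
        _, q, _, _ = multipletests([r.p_value for r in rows], method="fdr_bh")
        for r, qv in zip(rows, q):
            r.q_value = float(qv)
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


def enrichment_table(rows: List[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "name": r.name,
                "category": r.category,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "genes": ";".join(r.genes),
            }
            for r in rows
        ],
        columns=["term_id", "name", "category", "k", "n", "K", "N", "p_value", "q_value", "genes"],
    )
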