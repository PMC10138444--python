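"""Hypergeometric term enrichment of a gene set against a term map.

For a universe of N genes of which K carry a term, and a query set of n
genes of which k carry it, the enrichment p-value is the upper tail
P(X >= k) of the hypergeometric distribution.  Terms with p < 0.05 are
called enriched (raw p by default; an optional BH switch exists but is
off, matching the genome-background convention for GO/KEGG style maps).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


@dataclass
class EnrichmentResult:
    term_id: str
    k: int  # query genes with term
    K: int  # universe genes with term
    n: int  # query size
    N: int  # universe size
    p: float
    significant: bool


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (term_id, gene_id) -> {term: genes}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "gene_id"],
                     dtype=str, comment="#")
    out: dict[str, set[str]] = {}
    for term, gene in zip(df["term_id"], df["gene_id"]):
        out.setdefault(term, set()).add(gene)
    return out


def hypergeom_enrich(gene_set: Iterable[str],
                     term_map: Mapping[str, set[str]],
                     universe: Iterable[str] | None = None,
                     alpha: float = 0.05,
                     bh: bool = False) -> list[EnrichmentResult]:
    """Exact upper-tail hypergeometric enrichment per term.

    The universe defaults to the union of the term map's genes.  Query
    genes outside the universe are an error (they would silently bias
    every test).  Results are ordered by (p, term_id).
    """
    genes = set(gene_set)
    uni = set(universe) if universe is not None else set().union(*term_map.values())
    outside = sorted(genes - uni)
    if outside:
        raise ValueError(f"genes outside the universe: {outside[:10]}"
                         + ("..." if len(outside) > 10 else ""))
    N, n = len(uni), len(genes)
    results = []
    for term in sorted(term_map):
        members = term_map[term] & uni
        K = len(members)
        k = len(members & genes)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term, k, K, n, N, p, False))
    if bh:
        q = bh_adjust([r.p for r in results])
        for r, qv in zip(results, q):
            r.significant = qv < alpha
    else:
        for r in results:
            r.significant = r.p < alpha
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
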