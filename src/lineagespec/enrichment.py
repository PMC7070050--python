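"""Hypergeometric over-representation testing with BH FDR adjustment.

Shared machinery for GO-style term enrichment and TF-motif enrichment: an
upper-tail hypergeometric p-value P(X >= k) for drawing k annotated genes in
a query of size n from a universe of N genes of which K carry the term, and
the Benjamini-Hochberg step-up adjustment across tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "hypergeom_pvalue",
    "bh_adjust",
    "enrich",
    "read_annotation",
]


@dataclass
class EnrichmentResult:
    """One enrichment table (rows: term, N, K, n, k, p, FDR), FDR-sorted."""

    table: pd.DataFrame


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    N universe size, K term members in the universe, n query size, k overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(
            f"hypergeometric bounds violated: N={N}, K={K}, n={n}, k={k}"
        )
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def enrich(
    query: set[str],
    annotation: dict[str, set[str]],
    universe: set[str],
    min_term_size: int = 2,
) -> EnrichmentResult:
    """Hypergeometric enrichment of every term with >= 1 query member.

    ``annotation`` maps term_id -> gene set.  Terms are restricted to the
    universe before testing; terms with fewer than ``min_term_size`` universe
    members are skipped (untestable singletons inflate multiple testing).
    """
    stray = query - universe
    if stray:
        raise ValueError(
            f"query genes outside the universe: {sorted(stray)[:5]}"
        )
    N, n = len(universe), len(query)
    rows = []
    for term, genes in annotation.items():
        members = genes & universe
        K = len(members)
        if K < min_term_size:
            continue
        k = len(members & query)
        if k == 0:
            continue
        rows.append((term, N, K, n, k, hypergeom_pvalue(N, K, n, k)))
    if not rows:
        table = pd.DataFrame(
            columns=["term", "N", "K", "n", "k", "p", "FDR"]
        ).set_index("term")
        return EnrichmentResult(table=table)
    table = pd.DataFrame(rows, columns=["term", "N", "K", "n", "k", "p"])
    table["FDR"] = bh_adjust(table["p"].to_numpy())
    table = table.sort_values(["FDR", "p"]).set_index("term")
    return EnrichmentResult(table=table)


def read_annotation(tsv) -> dict[str, set[str]]:
    """Read a two-column (gene_id, term_id) TSV into term -> gene sets."""
    tab = pd.read_csv(tsv, sep="\t")
    if not {"gene_id", "term_id"}.issubset(tab.columns):
        raise ValueError("annotation TSV needs gene_id and term_id columns")
    out: dict[str, set[str]] = {}
    for term, grp in tab.groupby("term_id"):
        out[str(term)] = set(grp["gene_id"])
    return out
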