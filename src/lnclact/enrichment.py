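"""Hypergeometric over-representation analysis of gene sets.

One test per term: with N background genes, K of them carrying the term,
and a query of n annotated genes of which k carry the term,

    p = sum_{i=k}^{min(K,n)} C(K,i) C(N-K, n-i) / C(N,n),

computed in log-space for numerical stability.  A term is flagged
significant when the overlap is strictly greater than ``min_gene_count``
(default 5) and p is below ``alpha`` (default 0.05); BH-adjusted p-values
are reported alongside.  The background defaults to all genes present in
the supplied term annotation.  The rich factor k/K mirrors the usual
bubble-plot x-axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "hypergeom_upper_tail", "enrich"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    background_size: int     # N
    term_size: int           # K
    query_size: int          # n (annotated members only)
    overlap: int             # k
    p_value: float
    adjusted_p: float
    rich_factor: float       # k / K
    significant: bool


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), log-space summation."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"impossible configuration N={N} K={K} n={n} k={k}")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} exceeds min(K={K}, n={n})")
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def enrich(
    query_genes: set[str] | list[str],
    term_annotation: pd.DataFrame,
    background: set[str] | None = None,
    min_gene_count: int = 5,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-representation test of ``query_genes`` against every term.

    ``term_annotation`` needs columns ``gene_id``, ``term_id`` and
    optionally ``term_name``.  Query genes absent from the annotation are
    dropped from n (logged).  Significance requires overlap strictly
    greater than ``min_gene_count`` AND raw p below ``alpha``.  Results
    are sorted by (p, term id).
    """
    for col in ("gene_id", "term_id"):
        if col not in term_annotation.columns:
            raise ValueError(f"term annotation missing column {col!r}")
    annotated = set(term_annotation["gene_id"])
    if background is None:
        background = annotated
    else:
        background = set(background)
    if not background:
        raise ValueError("empty background")

    query = set(query_genes) & background
    dropped = len(set(query_genes)) - len(set(query_genes) & annotated)
    if dropped:
        logger.warning("dropped %d query genes absent from the annotation", dropped)
    query &= annotated
    N = len(background)
    n = len(query)

    names = {}
    if "term_name" in term_annotation.columns:
        names = dict(zip(term_annotation["term_id"], term_annotation["term_name"]))

    rows = []
    for term_id, sub in term_annotation.groupby("term_id"):
        term_genes = set(sub["gene_id"]) & background
        K = len(term_genes)
        if K < 1:
            continue
        k = len(term_genes & query)
        p = hypergeom_upper_tail(N, K, n, k)
        rows.append((str(term_id), K, k, p))
    if not rows:
        return []

    pvals = [r[3] for r in rows]
    padj = multipletests(pvals, method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            term_id=tid,
            term_name=str(names.get(tid, tid)),
            background_size=N,
            term_size=K,
            query_size=n,
            overlap=k,
            p_value=p,
            adjusted_p=float(a),
            rich_factor=k / K,
            significant=bool(k > min_gene_count and p < alpha),
        )
        for (tid, K, k, p), a in zip(rows, padj)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results
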