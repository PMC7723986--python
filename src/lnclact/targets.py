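"""Cis (genomic window) and trans (co-expression) target-gene prediction.

Cis targets are protein-coding genes whose span lies within a fixed window
(default 100 kb) upstream or downstream of a differentially expressed
lncRNA's span, strand-agnostic and boundary-inclusive.  Trans targets are
differentially expressed genes whose expression profile across all samples
correlates with the lncRNA's at |r| > 0.95 (strict) with p < 0.05, where p
comes from the t-statistic t = r * sqrt(n-2) / sqrt(1 - r^2) on n-2
degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .annotation import Annotation, Transcript, intervals_overlap

__all__ = [
    "CisTarget",
    "TransTarget",
    "find_cis_targets",
    "pearson_with_p",
    "find_trans_targets",
    "overlap_cis_trans",
]

logger = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW = 100_000


@dataclass(frozen=True)
class CisTarget:
    lncrna_id: str
    gene_id: str
    distance: int       # signed span gap: <0 upstream, >0 downstream, 0 overlap
    side: str           # upstream | downstream | overlapping


@dataclass(frozen=True)
class TransTarget:
    lncrna_id: str
    gene_id: str
    r: float
    p_value: float
    sign: str           # positive | negative


def _span_of(transcripts: list[Transcript]) -> tuple[str, int, int, str]:
    chrom = transcripts[0].chrom
    start = min(t.span[0] for t in transcripts)
    end = max(t.span[1] for t in transcripts)
    return chrom, start, end, transcripts[0].strand


def find_cis_targets(
    del_transcripts: dict[str, Transcript] | list[Transcript],
    genes: Annotation,
    window: int = DEFAULT_CIS_WINDOW,
) -> list[CisTarget]:
    """Genes within ``window`` bp of each lncRNA's span.

    A gene is reported iff its span intersects
    [lnc_start - window, lnc_end + window] on the same chromosome
    (boundary inclusive: a gap of exactly ``window`` is reported).  The
    distance is the gap between the two spans, 0 when they intersect;
    its sign and the ``side`` label are taken relative to the lncRNA's
    strand (a gene before the 5' end of the lncRNA is upstream).
    """
    if isinstance(del_transcripts, dict):
        lncs = list(del_transcripts.values())
    else:
        lncs = list(del_transcripts)
    out: list[CisTarget] = []
    for lnc in sorted(lncs, key=lambda t: t.transcript_id):
        ls, le = lnc.span
        for gid in sorted(genes.query_gene_spans(
                lnc.chrom, max(1, ls - window), le + window)):
            g = genes.genes[gid]
            if intervals_overlap(ls, le, g.span_start, g.span_end):
                out.append(CisTarget(lnc.transcript_id, gid, 0, "overlapping"))
                continue
            if g.span_end < ls:           # gene left of the lncRNA
                gap = ls - g.span_end
                left = True
            else:                          # gene right of the lncRNA
                gap = g.span_start - le
                left = False
            if gap > window:
                continue
            upstream = left if lnc.strand == "+" else not left
            out.append(CisTarget(
                lnc.transcript_id, gid,
                -gap if upstream else gap,
                "upstream" if upstream else "downstream",
            ))
    return out


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-distribution p-value.

    Requires length >= 3 and non-zero variance in both vectors; r = +/-1
    returns p = 0 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("vectors must have equal length")
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if 1.0 - abs(r) < 1e-12:   # exact linear dependence up to float error
        return (1.0 if r > 0 else -1.0), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * t_dist.sf(abs(t), n - 2))
    return r, min(1.0, p)


def find_trans_targets(
    del_fpkm: pd.DataFrame,
    deg_fpkm: pd.DataFrame,
    r_threshold: float = 0.95,
    alpha: float = 0.05,
    log_transform: bool = True,
    log_pseudo: float = 0.1,
) -> list[TransTarget]:
    """All DEL x DEG pairs with |r| > ``r_threshold`` (strict) and
    p < ``alpha``.

    Both tables must share sample columns.  By default the correlation is
    computed on log2(FPKM + ``log_pseudo``): with only five samples a raw-
    scale Pearson coefficient is dominated by the single most highly
    expressed sample, so the log scale is the robust default for
    co-expression screening (set ``log_transform=False`` for raw-scale r).
    Pairs where either vector has zero variance are skipped with a logged
    warning rather than erroring the run.  Output order is deterministic
    (lncRNA id, gene id).
    """
    if list(del_fpkm.columns) != list(deg_fpkm.columns):
        deg_fpkm = deg_fpkm[del_fpkm.columns]
    if log_transform:
        del_fpkm = np.log2(del_fpkm + log_pseudo)
        deg_fpkm = np.log2(deg_fpkm + log_pseudo)
    out: list[TransTarget] = []
    skipped = 0
    for lid in sorted(del_fpkm.index):
        x = del_fpkm.loc[lid].to_numpy(dtype=float)
        for gid in sorted(deg_fpkm.index):
            y = deg_fpkm.loc[gid].to_numpy(dtype=float)
            try:
                r, p = pearson_with_p(x, y)
            except ValueError:
                skipped += 1
                continue
            if abs(r) > r_threshold and p < alpha:
                out.append(TransTarget(lid, gid, r, p,
                                       "positive" if r > 0 else "negative"))
    if skipped:
        logger.warning("skipped %d zero-variance DEL/DEG pairs", skipped)
    return out


def overlap_cis_trans(
    cis: list[CisTarget], trans: list[TransTarget]
) -> set[str]:
    """Gene ids appearing both as cis and as trans targets."""
    return {c.gene_id for c in cis} & {t.gene_id for t in trans}
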