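"""Candidate lncRNA identification: the five-rule exclusion cascade.

A candidate transcript survives only if it

1. has at least two exons (``single_exon``),
2. is longer than 200 nt spliced (``too_short``; length 200 is removed),
3. reaches FPKM >= 0.5 in at least one sample (``low_fpkm``),
4. shares no exonic base with any known transcript, on either strand
   (``annotation_overlap``), and
5. shows no protein-coding potential (``coding_potential``), judged by an
   ORF-length rule optionally intersected with external tool verdicts.

All five rules are evaluated for every candidate (no short-circuiting) so
each verdict carries a complete audit trail; a transcript passes iff it
fails none.  Survivors are classified as lincRNA (intergenic) or antisense
(opposite-strand overlap with a known gene's span, exonic or intronic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Annotation, Transcript, spliced_sequence

__all__ = [
    "FilterConfig",
    "FilterVerdict",
    "longest_orf",
    "score_coding_potential",
    "run_filter_cascade",
    "classify_lncrna",
    "summarize_lncrna_set",
    "RULE_ORDER",
]

RULE_ORDER = ("single_exon", "too_short", "low_fpkm", "annotation_overlap",
              "coding_potential")

_STOPS = frozenset(("TAA", "TAG", "TGA"))


@dataclass
class FilterConfig:
    min_exons: int = 2
    min_length_nt: int = 200      # keep strictly > 200 nt
    min_fpkm: float = 0.5         # keep max-over-samples FPKM >= 0.5
    coding_orf_threshold_nt: int = 300  # ORF >= 300 nt (100 codons) => coding
    evidence_mode: str = "orf_only"     # or "intersection_with_external"

    def __post_init__(self) -> None:
        if min(self.min_exons, self.min_length_nt) <= 0 or self.min_fpkm <= 0 \
                or self.coding_orf_threshold_nt <= 0:
            raise ValueError("all filter thresholds must be > 0")
        if self.evidence_mode not in ("orf_only", "intersection_with_external"):
            raise ValueError(f"unknown evidence_mode {self.evidence_mode!r}")


@dataclass
class FilterVerdict:
    transcript_id: str
    passed: bool
    failed_rules: list[str] = field(default_factory=list)
    orf_length_nt: int = 0
    lnc_class: str = "NA"  # lincRNA | antisense | NA

    def __post_init__(self) -> None:
        if self.passed != (not self.failed_rules):
            raise ValueError("passed must equal 'failed_rules is empty'")
        if self.passed == (self.lnc_class == "NA"):
            raise ValueError("class must be set iff the transcript passed")


def longest_orf(sequence: str) -> int:
    """Length in nt (stop codon included) of the longest ATG-initiated,
    stop-terminated open reading frame across the three forward frames.

    The sequence is assumed to be strand-resolved already (5'->3').
    Codons containing N neither start, extend nor terminate an ORF: an open
    ORF hitting an ambiguous codon is discarded.  Returns 0 when no
    complete ORF exists.
    """
    seq = sequence.upper()
    n = len(seq)
    best = 0
    for frame in range(3):
        start = None  # position of the first ATG of the currently open ORF
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if "N" in codon:
                start = None
                continue
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, i + 3 - start)
                start = None
    return best


def score_coding_potential(
    transcript: Transcript,
    sequence: str,
    config: FilterConfig,
    external_verdicts: dict[str, dict[str, str]] | None = None,
) -> str:
    """Return ``"coding"`` or ``"noncoding"``.

    ``orf_only`` mode: coding iff the longest ORF reaches the threshold
    (inclusive).  ``intersection_with_external`` mode: a transcript is
    noncoding only when the ORF rule AND every supplied external tool agree
    on noncoding, mirroring a joint-exclusion use of several coding-potential
    predictors; any single "coding" call makes it coding.

    ``external_verdicts`` maps tool name -> {transcript_id: verdict}.
    """
    orf_call = ("coding" if longest_orf(sequence) >= config.coding_orf_threshold_nt
                else "noncoding")
    if config.evidence_mode == "orf_only" or not external_verdicts:
        return orf_call
    if orf_call == "coding":
        return "coding"
    for tool, table in external_verdicts.items():
        if transcript.transcript_id not in table:
            raise KeyError(
                f"external verdict file for {tool!r} lacks transcript "
                f"{transcript.transcript_id}"
            )
        if table[transcript.transcript_id] == "coding":
            return "coding"
    return "noncoding"


def run_filter_cascade(
    candidates: Annotation,
    known: Annotation,
    fpkm_table: pd.DataFrame,
    genome,
    config: FilterConfig | None = None,
    external_verdicts: dict[str, dict[str, str]] | None = None,
) -> list[FilterVerdict]:
    """Apply the five exclusion rules to every candidate transcript.

    ``fpkm_table`` must be indexed by transcript_id with one column per
    sample and cover every candidate.  Candidates whose id also appears in
    the known annotation are ignored (they are re-assembled known models,
    not identification candidates).  Verdicts are returned in deterministic
    (transcript_id-sorted) order.
    """
    config = config or FilterConfig()
    verdicts: list[FilterVerdict] = []
    for tid in sorted(candidates.transcripts):
        if tid in known.transcripts:
            continue
        t = candidates.transcripts[tid]
        if tid not in fpkm_table.index:
            raise KeyError(f"FPKM table has no row for candidate {tid}")
        failed: list[str] = []

        if t.n_exons < config.min_exons:
            failed.append("single_exon")
        if t.spliced_length <= config.min_length_nt:
            failed.append("too_short")
        if float(np.max(fpkm_table.loc[tid].to_numpy(dtype=float))) < config.min_fpkm:
            failed.append("low_fpkm")

        span = t.span
        hit_ids = known.query_exons(t.chrom, span[0], span[1])
        if _any_exonic_hit(t, known, hit_ids):
            failed.append("annotation_overlap")

        seq = spliced_sequence(t, genome)
        orf = longest_orf(seq)
        call = score_coding_potential(t, seq, config, external_verdicts)
        if call == "coding":
            failed.append("coding_potential")

        passed = not failed
        cls = classify_lncrna(t, known) if passed else "NA"
        verdicts.append(FilterVerdict(tid, passed, failed, orf, cls))
    return verdicts


def _any_exonic_hit(t: Transcript, known: Annotation, hit_ids: set[str]) -> bool:
    for kid in hit_ids:
        k = known.transcripts[kid]
        if k.chrom != t.chrom:
            continue
        for e in t.exons:
            for kx in k.exons:
                if kx.start <= e.end and e.start <= kx.end:
                    return True
    return False


def classify_lncrna(transcript: Transcript, known: Annotation) -> str:
    """``antisense`` iff the transcript overlaps (exonic or intronic, i.e.
    anywhere within the span) a known gene's span on the OPPOSITE strand;
    otherwise ``lincRNA``."""
    s, e = transcript.span
    for gid in known.query_gene_spans(transcript.chrom, s, e):
        if known.genes[gid].strand != transcript.strand:
            return "antisense"
    return "lincRNA"


def summarize_lncrna_set(
    verdicts: list[FilterVerdict],
    transcripts: dict[str, Transcript],
    length_bin_nt: int = 2000,
    orf_bin_nt: int = 50,
) -> dict:
    """Summary statistics of the surviving lncRNA set.

    Returns class counts with one-decimal percentages, spliced-length and
    ORF-length histograms (fixed-width bins), the exon-count histogram and
    the mean exon number (two decimals).
    """
    survivors = [v for v in verdicts if v.passed]
    n = len(survivors)
    class_counts: dict[str, int] = {}
    for v in survivors:
        class_counts[v.lnc_class] = class_counts.get(v.lnc_class, 0) + 1
    class_pct = {c: round(100.0 * k / n, 1) if n else 0.0
                 for c, k in class_counts.items()}

    length_hist: dict[str, int] = {}
    orf_hist: dict[str, int] = {}
    exon_hist: dict[int, int] = {}
    exon_total = 0
    for v in survivors:
        t = transcripts[v.transcript_id]
        lb = (t.spliced_length - 1) // length_bin_nt
        lkey = f"{lb * length_bin_nt + 1}-{(lb + 1) * length_bin_nt}"
        length_hist[lkey] = length_hist.get(lkey, 0) + 1
        ob = max(v.orf_length_nt - 1, 0) // orf_bin_nt
        okey = f"{ob * orf_bin_nt + 1}-{(ob + 1) * orf_bin_nt}"
        orf_hist[okey] = orf_hist.get(okey, 0) + 1
        exon_hist[t.n_exons] = exon_hist.get(t.n_exons, 0) + 1
        exon_total += t.n_exons
    return {
        "n_lncrna": n,
        "class_counts": dict(sorted(class_counts.items())),
        "class_pct": dict(sorted(class_pct.items())),
        "length_hist": dict(sorted(length_hist.items(),
                                   key=lambda kv: int(kv[0].split("-")[0]))),
        "orf_length_hist": dict(sorted(orf_hist.items(),
                                       key=lambda kv: int(kv[0].split("-")[0]))),
        "exon_count_hist": dict(sorted(exon_hist.items())),
        "mean_exon_number": round(exon_total / n, 2) if n else 0.0,
    }
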