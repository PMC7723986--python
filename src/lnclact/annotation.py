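"""Genomic feature model: exons, transcripts, gene models and an indexed annotation.

Coordinates follow the GTF convention everywhere at the API surface:
1-based, closed intervals (``start`` and ``end`` are both included).  The
half-open convention required by the interval index is confined to this
module's internals and never exposed.

Only ``exon`` feature lines are semantic in GTF input; everything else is
ignored.  Transcripts with unknown strand "." are rejected at parse time
because every downstream rule (antisense classification, ORF scanning) is
strand-dependent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from intervaltree import IntervalTree

__all__ = [
    "Exon",
    "Transcript",
    "GeneModel",
    "Annotation",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "spliced_sequence",
    "exonic_overlap",
    "reverse_complement",
    "BIOTYPES",
]

BIOTYPES = ("known_coding", "known_noncoding", "novel_candidate")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be interpreted."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def intervals_overlap(s1: int, e1: int, s2: int, e2: int) -> bool:
    """Closed-interval overlap: true iff [s1,e1] and [s2,e2] share >= 1 base."""
    return s1 <= e2 and s2 <= e1


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"exon start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"exon end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Exon]
    biotype: str = "novel_candidate"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap "
                    f"({a.start}-{a.end} vs {b.start}-{b.end})"
                )
        for e in self.exons:
            if e.chrom != self.chrom:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on {e.chrom}, "
                    f"transcript on {self.chrom}"
                )

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span_start(self) -> int:
        return min(t.span[0] for t in self.transcripts)

    @property
    def span_end(self) -> int:
        return max(t.span[1] for t in self.transcripts)


class Annotation:
    """A set of gene models with per-chromosome interval indexes.

    ``query_exons``/``query_gene_spans`` answer closed-interval overlap
    queries; results are verified against a linear scan in the test suite.
    """

    def __init__(self, transcripts: list[Transcript] | None = None):
        self.genes: dict[str, GeneModel] = {}
        self.transcripts: dict[str, Transcript] = {}
        self._exon_index: dict[str, IntervalTree] | None = None
        self._gene_index: dict[str, IntervalTree] | None = None
        for t in transcripts or []:
            self.add_transcript(t)

    def add_transcript(self, t: Transcript) -> None:
        if t.transcript_id in self.transcripts:
            raise ValueError(f"duplicate transcript_id {t.transcript_id}")
        self.transcripts[t.transcript_id] = t
        gene = self.genes.get(t.gene_id)
        if gene is None:
            gene = GeneModel(t.gene_id, t.chrom, t.strand)
            self.genes[t.gene_id] = gene
        gene.transcripts.append(t)
        self._exon_index = None
        self._gene_index = None

    def __len__(self) -> int:
        return len(self.transcripts)

    def _build_indexes(self) -> None:
        exon_idx: dict[str, IntervalTree] = {}
        gene_idx: dict[str, IntervalTree] = {}
        for t in self.transcripts.values():
            tree = exon_idx.setdefault(t.chrom, IntervalTree())
            for e in t.exons:
                tree.addi(e.start, e.end + 1, t.transcript_id)  # internal half-open
        for g in self.genes.values():
            tree = gene_idx.setdefault(g.chrom, IntervalTree())
            tree.addi(g.span_start, g.span_end + 1, g.gene_id)
        self._exon_index = exon_idx
        self._gene_index = gene_idx

    def query_exons(self, chrom: str, start: int, end: int) -> set[str]:
        """Transcript ids with >= 1 exonic base in the closed interval."""
        if self._exon_index is None:
            self._build_indexes()
        tree = self._exon_index.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end + 1)}

    def query_gene_spans(self, chrom: str, start: int, end: int) -> set[str]:
        """Gene ids whose span shares >= 1 base with the closed interval."""
        if self._gene_index is None:
            self._build_indexes()
        tree = self._gene_index.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end + 1)}


# --- GTF I/O -----------------------------------------------------------------

# accepts both  key "value";  and  key=value  attribute dialects
_ATTR_QUOTED = re.compile(r'(\w+)\s+"([^"]*)"')
_ATTR_EQ = re.compile(r"(\w+)=([^;\s]+)")


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs = dict(_ATTR_QUOTED.findall(attr_field))
    if not attrs:
        attrs = dict(_ATTR_EQ.findall(attr_field))
    return attrs


def read_gtf(path) -> Annotation:
    """Parse a GTF file into an :class:`Annotation`.

    Exon feature lines are grouped into transcripts by their
    ``transcript_id`` attribute; coordinates are preserved exactly.
    Malformed lines raise :class:`GtfParseError` naming the line number.
    """
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-delimited fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-"):
                raise GtfParseError(
                    f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}"
                )
            attrs = _parse_attributes(attr_s)
            tid = attrs.get("transcript_id")
            if not tid:
                raise GtfParseError(f"{path}:{lineno}: exon missing transcript_id")
            gid = attrs.get("gene_id")
            if not gid:
                raise GtfParseError(f"{path}:{lineno}: exon missing gene_id")
            rec = per_tx.get(tid)
            if rec is None:
                rec = {
                    "gene_id": gid,
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "biotype": attrs.get("transcript_biotype", "novel_candidate"),
                }
                per_tx[tid] = rec
                order.append(tid)
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise GtfParseError(
                    f"{path}:{lineno}: transcript {tid} changes chrom/strand"
                )
            try:
                rec["exons"].append(Exon(chrom, start, end))
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: {exc}") from exc
    ann = Annotation()
    for tid in order:
        rec = per_tx[tid]
        ann.add_transcript(
            Transcript(tid, rec["gene_id"], rec["chrom"], rec["strand"],
                       rec["exons"], rec["biotype"])
        )
    return ann


def write_gtf(annotation: Annotation, path) -> None:
    """Write exon lines for every transcript, deterministically ordered by
    (chrom, span start, transcript_id); byte-identical across runs."""
    txs = sorted(
        annotation.transcripts.values(),
        key=lambda t: (t.chrom, t.span[0], t.transcript_id),
    )
    with open(path, "w") as fh:
        for t in txs:
            for e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'transcript_biotype "{t.biotype}";'
                )
                fh.write(
                    f"{t.chrom}\tlnclact\texon\t{e.start}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# --- sequence extraction -----------------------------------------------------

def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """1-based closed fetch from a pyfaidx.Fasta or a plain dict of strings."""
    try:
        record = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} not in genome") from exc
    seq = str(record[start - 1:end])
    if len(seq) != end - start + 1:
        raise IndexError(
            f"coordinates {start}-{end} out of range for chromosome {chrom}"
        )
    return seq


def spliced_sequence(transcript: Transcript, genome) -> str:
    """Spliced transcript sequence, 5'->3'.

    Exon subsequences are concatenated in genomic order; for "-" strand
    transcripts the reverse complement of the concatenation is returned.
    ``genome`` may be a :class:`pyfaidx.Fasta` or a mapping of chromosome
    name to sequence string.
    """
    parts = [_fetch(genome, transcript.chrom, e.start, e.end) for e in transcript.exons]
    seq = "".join(parts).upper()
    if transcript.strand == "-":
        seq = reverse_complement(seq)
    return seq


def exonic_overlap(t1: Transcript, t2: Transcript, require_same_strand: bool = False) -> bool:
    """True iff some exon of ``t1`` shares >= 1 base with some exon of ``t2``.

    With ``require_same_strand`` the overlap only counts when both
    transcripts are on the same strand.
    """
    if t1.chrom != t2.chrom:
        return False
    if require_same_strand and t1.strand != t2.strand:
        return False
    s1, e1 = t1.span
    s2, e2 = t2.span
    if not intervals_overlap(s1, e1, s2, e2):
        return False
    for a in t1.exons:
        for b in t2.exons:
            if intervals_overlap(a.start, a.end, b.start, b.end):
                return True
    return False
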