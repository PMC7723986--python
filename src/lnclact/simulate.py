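"""Seeded synthetic-data generator for the whole pipeline.

Emulates the study design the pipeline targets: a two-group bulk RNA-seq
comparison of mammary tissue with 2 lactation (LP) and 3 dry-period (DP)
libraries.  Every input the pipeline consumes is generated with planted
ground truth:

* a genome (FASTA) and a known annotation (GTF) of multi-exon coding genes
  whose spliced sequences carry ORFs >= 300 nt;
* a candidate annotation (GTF) holding the known transcripts, planted true
  lncRNAs (intergenic and intronic-antisense), and decoy transcripts each
  violating exactly one identification filter;
* NB-distributed fragment counts (Var = mu + phi mu^2) with planted
  differential expression at |log2FC| = 2 and planted high-correlation
  trans pairs driven by a shared per-sample latent factor;
* a gene->term annotation with one strongly enriched term;
* qPCR Ct tables consistent with the planted fold changes, with constant
  reference genes (HMBS, YWHAZ).

Each generator stage draws from its own RNG stream derived from the master
seed and the stage name, so adding a stage never perturbs earlier draws.
Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Annotation, Exon, Transcript, write_gtf, reverse_complement
from .identify import longest_orf

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConfigurationError",
    "generate_genome_and_annotation",
    "simulate_counts",
    "generate_term_annotation",
    "simulate_qpcr",
    "write_bundle",
]


class ConfigurationError(ValueError):
    """Invalid or infeasible simulation configuration."""


DECOY_MODES = ("single_exon", "too_short", "low_fpkm", "annotation_overlap",
               "coding_potential")

_BASES = np.array(list("ACGT"))
_STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOP_CODONS
)


@dataclass
class SimulationConfig:
    seed: int = 7
    n_chromosomes: int = 2
    chrom_length_bp: int = 1_000_000
    n_coding_genes: int = 100
    n_lincrna: int = 30
    n_antisense: int = 10
    n_decoys_per_mode: int = 10
    n_lp: int = 2
    n_dp: int = 3
    n_de_lncrna: int = 10          # plain planted-DE lncRNAs (half up, half down)
    n_de_genes: int = 20           # plain planted-DE coding genes
    effect_log2fc: float = 2.0
    phi: float = 0.1               # NB dispersion, Var = mu + phi mu^2
    library_sizes: tuple = (20_000_000, 19_000_000, 21_000_000,
                            18_000_000, 22_000_000)
    n_trans_lnc: int = 2           # trans hubs
    genes_per_trans_lnc: int = 8
    trans_latent_sd_log2: float = 3.0
    n_terms: int = 20
    qpcr_noise_sd: float = 0.15    # Ct units
    qpcr_n_features: int = 10
    low_fpkm_target: float = 0.01  # expected FPKM of the low-expression decoys

    def __post_init__(self) -> None:
        ints = (self.n_chromosomes, self.chrom_length_bp, self.n_coding_genes,
                self.n_lincrna, self.n_antisense, self.n_decoys_per_mode,
                self.n_lp, self.n_dp, self.n_terms)
        if any(v < 0 for v in ints):
            raise ConfigurationError("all counts must be >= 0")
        if self.n_chromosomes < 1 or self.n_lp < 1 or self.n_dp < 1:
            raise ConfigurationError("need >= 1 chromosome and >= 1 sample per group")
        if self.phi < 0:
            raise ConfigurationError("phi must be >= 0")
        if len(self.library_sizes) != self.n_samples:
            raise ConfigurationError(
                f"need {self.n_samples} library sizes, got {len(self.library_sizes)}"
            )
        if self.n_coding_genes < self.n_antisense + self.n_decoys_per_mode:
            raise ConfigurationError(
                "need enough coding genes to host antisense lncRNAs and "
                "overlap decoys"
            )
        n_true = self.n_lincrna + self.n_antisense
        if self.n_de_lncrna + self.n_trans_lnc > n_true:
            raise ConfigurationError("more planted DE/trans lncRNAs than lncRNAs")
        if self.n_de_genes + self.n_trans_lnc * self.genes_per_trans_lnc \
                > self.n_coding_genes:
            raise ConfigurationError("more planted DE/trans genes than genes")

    @property
    def n_samples(self) -> int:
        return self.n_lp + self.n_dp

    @property
    def sample_names(self) -> list[str]:
        return [f"LP{i+1}" for i in range(self.n_lp)] + \
               [f"DP{i+1}" for i in range(self.n_dp)]

    @property
    def groups(self) -> dict[str, str]:
        return {s: ("LP" if s.startswith("LP") else "DP")
                for s in self.sample_names}


@dataclass
class GroundTruth:
    """Planted truth for every stage; ids always exist in the emitted files."""

    true_lncrnas: dict = field(default_factory=dict)      # id -> class
    decoys: dict = field(default_factory=dict)            # id -> failure mode
    de_log2fc: dict = field(default_factory=dict)         # id -> signed log2FC
    trans_pairs: list = field(default_factory=list)       # (lnc id, gene id)
    cis_pairs: list = field(default_factory=list)         # (lnc id, gene id, gap bp)
    enriched_term: str | None = None
    enriched_term_targets: list = field(default_factory=list)
    qpcr_features: list = field(default_factory=list)
    transcript_lengths: dict = field(default_factory=dict)  # id -> spliced nt
    coding_gene_ids: list = field(default_factory=list)

    @property
    def trans_lncrnas(self) -> list:
        return sorted({l for l, _ in self.trans_pairs})

    @property
    def trans_genes(self) -> list:
        return sorted({g for _, g in self.trans_pairs})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _stage_rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    """One RNG stream per stage, keyed by (master seed, crc32(stage))."""
    return np.random.default_rng([config.seed, zlib.crc32(stage.encode())])


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _split_lengths(rng, total: int, n: int, min_len: int) -> list[int]:
    """Split ``total`` into n parts, each >= min_len."""
    if total < n * min_len:
        raise ConfigurationError(f"cannot split {total} into {n} parts >= {min_len}")
    extra = rng.multinomial(total - n * min_len, np.full(n, 1.0 / n))
    return [min_len + int(e) for e in extra]


def _design_coding_sequence(rng, total: int, min_orf_nt: int = 300) -> str:
    """Random sequence of length ``total`` containing a complete ORF of at
    least ``min_orf_nt`` nt (start and stop codons included)."""
    n_codons = int(rng.integers(min_orf_nt // 3, min(total // 3, min_orf_nt // 3 + 60)))
    orf = "ATG" + "".join(
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)
    ) + _STOP_CODONS[int(rng.integers(0, 3))]
    prefix_len = int(rng.integers(0, total - len(orf) + 1))
    suffix_len = total - len(orf) - prefix_len
    return _random_bases(rng, prefix_len) + orf + _random_bases(rng, suffix_len)


# --- genome / annotation ----------------------------------------------------


@dataclass
class _Locus:
    kind: str            # gene | linc | single_exon | too_short | low_fpkm | coding_potential
    index: int
    exon_lengths: list[int]
    intron_lengths: list[int]
    host_intron: int | None = None  # index of the widened intron (antisense hosts)


def _plan_loci(config: SimulationConfig, rng) -> list[_Locus]:
    loci: list[_Locus] = []
    for i in range(config.n_coding_genes):
        is_host = i < config.n_antisense
        n_exons = int(rng.integers(3 if is_host else 2, 11))
        exon_lens = [int(rng.integers(80, 301)) for _ in range(n_exons)]
        if sum(exon_lens) < 450:  # room for the planted ORF
            exon_lens[-1] += 450 - sum(exon_lens)
        intron_lens = [int(rng.integers(100, 501)) for _ in range(n_exons - 1)]
        host_intron = None
        if is_host:
            host_intron = int(rng.integers(0, n_exons - 1))
            intron_lens[host_intron] = int(rng.integers(1600, 2401))
        loci.append(_Locus("gene", i, exon_lens, intron_lens, host_intron))
    for i in range(config.n_lincrna):
        n_exons = int(rng.integers(2, 6))
        # spliced lengths mostly 200-2000 nt, all > 200
        total = int(rng.integers(max(250, n_exons * 80 + 20), 2501))
        loci.append(_Locus("linc", i, _split_lengths(rng, total, n_exons, 80),
                           [int(rng.integers(100, 501)) for _ in range(n_exons - 1)]))
    for i in range(config.n_decoys_per_mode):
        loci.append(_Locus("single_exon", i, [int(rng.integers(400, 1501))], []))
    for i in range(config.n_decoys_per_mode):
        total = 200 if i == 0 else int(rng.integers(140, 201))  # one exactly at the boundary
        loci.append(_Locus("too_short", i, _split_lengths(rng, total, 2, 60),
                           [int(rng.integers(100, 501))]))
    for i in range(config.n_decoys_per_mode):
        n_exons = int(rng.integers(2, 5))
        total = int(rng.integers(800, 1201))
        loci.append(_Locus("low_fpkm", i, _split_lengths(rng, total, n_exons, 80),
                           [int(rng.integers(100, 501)) for _ in range(n_exons - 1)]))
    for i in range(config.n_decoys_per_mode):
        n_exons = int(rng.integers(2, 5))
        total = int(rng.integers(550, 1501))
        loci.append(_Locus("coding_potential", i,
                           _split_lengths(rng, total, n_exons, 120),
                           [int(rng.integers(100, 501)) for _ in range(n_exons - 1)]))
    # deterministic interleave so feature kinds mix along each chromosome
    order = rng.permutation(len(loci))
    return [loci[i] for i in order]


def _place_exons(start: int, exon_lens, intron_lens) -> list[tuple[int, int]]:
    coords = []
    pos = start
    for i, el in enumerate(exon_lens):
        coords.append((pos, pos + el - 1))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    return coords


def generate_genome_and_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, str], Annotation, Annotation, GroundTruth]:
    """Generate (genome, known annotation, candidate annotation, truth).

    The genome is returned as a dict of chromosome name -> sequence; the
    known annotation holds the coding genes, the candidate annotation holds
    the known transcripts plus planted lncRNAs and decoys.
    """
    rng = _stage_rng(config, "genome")
    gt = GroundTruth()

    loci = _plan_loci(config, rng)
    chrom_names = [f"chr{i+1}" for i in range(config.n_chromosomes)]
    genome_arrays = {
        c: np.array(list(_random_bases(rng, config.chrom_length_bp)))
        for c in chrom_names
    }

    # sequential packing, round-robin across chromosomes
    cursors = {c: 1000 for c in chrom_names}
    placements = []  # (locus, chrom, exon_coords, strand)
    for j, locus in enumerate(loci):
        chrom = chrom_names[j % config.n_chromosomes]
        gap = int(rng.integers(400, 1501))
        start = cursors[chrom] + gap
        coords = _place_exons(start, locus.exon_lengths, locus.intron_lengths)
        end = coords[-1][1]
        if end > config.chrom_length_bp - 1000:
            raise ConfigurationError(
                f"infeasible packing: {chrom} overflows at locus {j} "
                f"(end {end} > {config.chrom_length_bp - 1000})"
            )
        cursors[chrom] = end
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        placements.append((locus, chrom, coords, strand))

    known = Annotation()
    candidates = Annotation()

    def write_designed(chrom: str, coords, strand: str, spliced: str) -> None:
        """Overwrite genomic exon bases so the spliced transcript sequence
        equals ``spliced`` (strand-resolved)."""
        genomic = spliced if strand == "+" else reverse_complement(spliced)
        pos = 0
        for s, e in coords:
            seg = genomic[pos:pos + (e - s + 1)]
            genome_arrays[chrom][s - 1:e] = list(seg)
            pos += len(seg)

    def spliced_of(chrom: str, coords, strand: str) -> str:
        seq = "".join(
            "".join(genome_arrays[chrom][s - 1:e]) for s, e in coords
        )
        return reverse_complement(seq) if strand == "-" else seq

    def redraw_noncoding(chrom: str, coords, strand: str,
                         threshold: int = 300, free=None) -> None:
        """Re-randomize the free exon bases until the spliced ORF < threshold."""
        free = free if free is not None else coords
        for _ in range(200):
            if longest_orf(spliced_of(chrom, coords, strand)) < threshold:
                return
            for s, e in free:
                genome_arrays[chrom][s - 1:e] = list(_random_bases(rng, e - s + 1))
        raise ConfigurationError("could not draw a noncoding sequence")

    gene_placements = []   # for antisense/overlap hosting, in gene index order
    for locus, chrom, coords, strand in placements:
        exons = [Exon(chrom, s, e) for s, e in coords]
        total = sum(e.length for e in exons)
        if locus.kind == "gene":
            gid = f"GENE_{locus.index + 1:04d}"
            tid = f"{gid}.t1"
            write_designed(chrom, coords, strand,
                           _design_coding_sequence(rng, total))
            t = Transcript(tid, gid, chrom, strand, exons, "known_coding")
            known.add_transcript(t)
            candidates.add_transcript(
                Transcript(tid, gid, chrom, strand, exons, "known_coding"))
            gt.coding_gene_ids.append(gid)
            gt.transcript_lengths[tid] = total
            gene_placements.append((locus, chrom, coords, strand, gid))
        elif locus.kind == "linc":
            tid = f"LNC_L{locus.index + 1:04d}"
            redraw_noncoding(chrom, coords, strand)
            candidates.add_transcript(
                Transcript(tid, tid, chrom, strand, exons))
            gt.true_lncrnas[tid] = "lincRNA"
            gt.transcript_lengths[tid] = total
        elif locus.kind == "coding_potential":
            tid = f"DECOY_ORF_{locus.index + 1:02d}"
            write_designed(chrom, coords, strand,
                           _design_coding_sequence(rng, total))
            candidates.add_transcript(
                Transcript(tid, tid, chrom, strand, exons))
            gt.decoys[tid] = "coding_potential"
            gt.transcript_lengths[tid] = total
        else:  # single_exon, too_short, low_fpkm
            tag = {"single_exon": "SE", "too_short": "LEN", "low_fpkm": "FPKM"}[locus.kind]
            tid = f"DECOY_{tag}_{locus.index + 1:02d}"
            redraw_noncoding(chrom, coords, strand)
            candidates.add_transcript(
                Transcript(tid, tid, chrom, strand, exons))
            gt.decoys[tid] = locus.kind
            gt.transcript_lengths[tid] = total

    gene_placements.sort(key=lambda p: p[0].index)

    # antisense lncRNAs: exons inside the widened intron of a host gene,
    # opposite strand -> they overlap the gene span but no known exon
    for i in range(config.n_antisense):
        locus, chrom, coords, strand, gid = gene_placements[i]
        hi = locus.host_intron
        intron_start = coords[hi][1] + 1
        intron_end = coords[hi + 1][0] - 1
        len1 = int(rng.integers(110, 181))
        len2 = int(rng.integers(110, 181))
        gap = int(rng.integers(100, 301))
        s1 = intron_start + 50
        e1 = s1 + len1 - 1
        s2 = e1 + 1 + gap
        e2 = s2 + len2 - 1
        if e2 > intron_end - 50:
            raise ConfigurationError("antisense lncRNA does not fit host intron")
        as_strand = "-" if strand == "+" else "+"
        as_coords = [(s1, e1), (s2, e2)]
        tid = f"LNC_A{i + 1:04d}"
        redraw_noncoding(chrom, as_coords, as_strand)
        candidates.add_transcript(
            Transcript(tid, tid, chrom, as_strand,
                       [Exon(chrom, s, e) for s, e in as_coords]))
        gt.true_lncrnas[tid] = "antisense"
        gt.transcript_lengths[tid] = len1 + len2

    # annotation-overlap decoys: one exon inside a host gene exon (alternating
    # same/opposite strand to exercise the strand-agnostic removal rule),
    # one free exon just downstream of the gene span
    for i in range(config.n_decoys_per_mode):
        locus, chrom, coords, strand, gid = \
            gene_placements[config.n_antisense + i]
        hx_s, hx_e = coords[0]
        ov_len = min(150, hx_e - hx_s + 1)
        e1 = (hx_s, hx_s + ov_len - 1)
        span_end = coords[-1][1]
        free_len = int(rng.integers(150, 201))
        e2 = (span_end + 100, span_end + 100 + free_len - 1)
        d_strand = strand if i % 2 == 0 else ("-" if strand == "+" else "+")
        tid = f"DECOY_OVL_{i + 1:02d}"
        redraw_noncoding(chrom, [e1, e2], d_strand, free=[e2])
        candidates.add_transcript(
            Transcript(tid, tid, chrom, d_strand,
                       [Exon(chrom, s, e) for s, e in [e1, e2]]))
        gt.decoys[tid] = "annotation_overlap"
        gt.transcript_lengths[tid] = ov_len + free_len

    # planted cis pairs: every (true lncRNA, coding gene) whose spans sit
    # within 100 kb on the same chromosome, found by brute-force scan
    lnc_spans = {}
    for tid in gt.true_lncrnas:
        t = candidates.transcripts[tid]
        lnc_spans[tid] = (t.chrom, t.span[0], t.span[1])
    for tid in sorted(lnc_spans):
        lc, ls, le = lnc_spans[tid]
        for gid in gt.coding_gene_ids:
            g = known.genes[gid]
            if g.chrom != lc:
                continue
            gap = max(0, max(g.span_start - le, ls - g.span_end))
            if gap <= 100_000:
                gt.cis_pairs.append((tid, gid, int(gap)))

    # planted expression roles, drawn from a dedicated stream
    prng = _stage_rng(config, "plant")
    lnc_ids = sorted(gt.true_lncrnas)
    gene_ids = list(gt.coding_gene_ids)
    lnc_pick = [lnc_ids[i] for i in prng.permutation(len(lnc_ids))]
    gene_pick = [gene_ids[i] for i in prng.permutation(len(gene_ids))]
    de_lnc = lnc_pick[:config.n_de_lncrna]
    trans_lnc = lnc_pick[config.n_de_lncrna:
                         config.n_de_lncrna + config.n_trans_lnc]
    de_genes = gene_pick[:config.n_de_genes]
    trans_genes = gene_pick[config.n_de_genes:
                            config.n_de_genes +
                            config.n_trans_lnc * config.genes_per_trans_lnc]
    for j, fid in enumerate(de_lnc):
        gt.de_log2fc[fid] = config.effect_log2fc * (1 if j % 2 == 0 else -1)
    for j, gid in enumerate(de_genes):
        tid = f"{gid}.t1"
        gt.de_log2fc[tid] = config.effect_log2fc * (1 if j % 2 == 0 else -1)
    for h, lid in enumerate(trans_lnc):
        for gid in trans_genes[h * config.genes_per_trans_lnc:
                               (h + 1) * config.genes_per_trans_lnc]:
            gt.trans_pairs.append((lid, gid))
    gt.enriched_term_targets = gt.trans_genes

    genome = {c: "".join(genome_arrays[c]) for c in chrom_names}
    return genome, known, candidates, gt


# --- counts ------------------------------------------------------------------


def simulate_counts(
    config: SimulationConfig, gt: GroundTruth
) -> tuple[pd.DataFrame, dict[str, str], pd.Series]:
    """NB fragment counts (features x samples) with the planted structure.

    Non-DE features share a mean across groups (scaled by library size);
    plain planted-DE features differ by the planted log2FC split
    symmetrically around the base; each planted trans hub shares a strong
    per-sample log-normal latent factor between its lncRNA and its target
    genes (and carries no group effect, so the correlation is the only
    planted signal); the low-expression decoys sit far below the
    FPKM >= 0.5 identification threshold in every sample.
    """
    if config.phi < 0:
        raise ConfigurationError("phi must be >= 0")
    rng = _stage_rng(config, "counts")
    samples = config.sample_names
    groups = config.groups
    libs = pd.Series(list(config.library_sizes), index=samples, dtype=float)

    feature_ids = sorted(gt.transcript_lengths)
    trans_members: dict[str, int] = {}   # feature -> hub index
    for h, lid in enumerate(gt.trans_lncrnas):
        trans_members[lid] = h
        for l, g in gt.trans_pairs:
            if l == lid:
                trans_members[f"{g}.t1"] = h
    # one latent per hub per sample, shared by all members of the hub
    latent = 2.0 ** rng.normal(
        0.0, config.trans_latent_sd_log2,
        size=(max(len(gt.trans_lncrnas), 1), len(samples)),
    )

    mu = np.zeros((len(feature_ids), len(samples)))
    group_sign = np.array([1.0 if groups[s] == "LP" else -1.0 for s in samples])
    for i, fid in enumerate(feature_ids):
        length = gt.transcript_lengths[fid]
        if fid in gt.decoys and gt.decoys[fid] == "low_fpkm":
            base_fpkm = config.low_fpkm_target
        elif fid in gt.de_log2fc:
            base_fpkm = float(rng.uniform(25.0, 60.0))
        elif fid in trans_members:
            base_fpkm = 20.0
        elif fid.startswith("LNC_") or fid.startswith("DECOY_"):
            base_fpkm = float(10.0 ** rng.uniform(0.5, 1.5))
        else:
            base_fpkm = float(10.0 ** rng.uniform(0.7, 1.7))
        row = base_fpkm * length * libs.to_numpy() / 1e9
        if fid in gt.de_log2fc:
            row = row * 2.0 ** (group_sign * gt.de_log2fc[fid] / 2.0)
        if fid in trans_members:
            hub = trans_members[fid]
            # hub members share both a group effect (alternating direction)
            # and the latent factor, so planted pairs are DE and co-expressed
            hub_lfc = config.effect_log2fc * (1.0 if hub % 2 == 0 else -1.0)
            row = row * 2.0 ** (group_sign * hub_lfc / 2.0)
            row = row * latent[hub]
        mu[i] = row

    if config.phi == 0.0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / config.phi
        counts = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame(counts.astype(np.int64), index=feature_ids, columns=samples)
    df.index.name = "transcript_id"
    return df, groups, libs


# --- term annotation ---------------------------------------------------------


def generate_term_annotation(
    config: SimulationConfig, gt: GroundTruth
) -> pd.DataFrame:
    """Gene -> term mapping with one planted enriched term.

    Every coding gene carries 1-5 of the ``n_terms`` terms.  The planted
    term covers >= 80% of the planted target genes and <= 10% of the
    remaining background; with a single term it is assigned to all genes
    (and can never be enriched).
    """
    if config.n_terms < 1:
        raise ConfigurationError("need at least one term")
    rng = _stage_rng(config, "terms")
    genes = list(gt.coding_gene_ids)
    terms = [f"TERM_{i + 1:03d}" for i in range(config.n_terms)]
    rows: list[tuple[str, str, str]] = []

    if config.n_terms == 1:
        gt.enriched_term = terms[0]
        for g in genes:
            rows.append((g, terms[0], f"pathway {terms[0]}"))
        return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"])

    enriched = terms[0]
    gt.enriched_term = enriched
    targets = list(gt.enriched_term_targets)
    background = [g for g in genes if g not in set(targets)]
    n_cover = max(1, int(np.ceil(0.9 * len(targets)))) if targets else 0
    covered = set(targets[i] for i in rng.permutation(len(targets))[:n_cover])
    n_bg = int(0.05 * len(background))
    covered |= {background[i] for i in rng.permutation(len(background))[:n_bg]}

    other_terms = terms[1:]
    for g in genes:
        assigned = set()
        if g in covered:
            assigned.add(enriched)
        k = int(rng.integers(1, 6))
        for i in rng.permutation(len(other_terms))[:k]:
            assigned.add(other_terms[i])
        for t in sorted(assigned):
            rows.append((g, t, f"pathway {t}"))
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"])


# --- qPCR --------------------------------------------------------------------


def simulate_qpcr(config: SimulationConfig, gt: GroundTruth) -> pd.DataFrame:
    """Ct table (features x samples) including HMBS and YWHAZ rows.

    Ct = intercept - log2(relative expression) + Gaussian noise; reference
    genes are constant across groups up to noise, and target expression
    follows the planted log2 fold changes (split symmetrically LP vs DP).
    """
    rng = _stage_rng(config, "qpcr")
    samples = config.sample_names
    groups = config.groups
    de_lnc = sorted(f for f in gt.de_log2fc if f in gt.true_lncrnas)
    features = de_lnc[:config.qpcr_n_features]
    gt.qpcr_features = features

    group_sign = np.array([1.0 if groups[s] == "LP" else -1.0 for s in samples])
    rows = {}
    for fid in features:
        log2_rel = group_sign * gt.de_log2fc[fid] / 2.0
        rows[fid] = 30.0 - log2_rel + rng.normal(0.0, config.qpcr_noise_sd,
                                                 len(samples))
    rows["HMBS"] = 22.0 + rng.normal(0.0, config.qpcr_noise_sd, len(samples))
    rows["YWHAZ"] = 24.0 + rng.normal(0.0, config.qpcr_noise_sd, len(samples))
    df = pd.DataFrame(rows, index=samples).T
    df.index.name = "feature_id"
    return df


# --- bundle writer -----------------------------------------------------------


def _write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bundle(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Generate everything and write the full input bundle to ``outdir``.

    Files: genome.fa, known.gtf, candidates.gtf, counts.tsv, samples.tsv,
    terms.tsv, qpcr_ct.tsv, ground_truth.json.  Byte-identical under a
    fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, known, candidates, gt = generate_genome_and_annotation(config)
    counts, groups, libs = simulate_counts(config, gt)
    terms = generate_term_annotation(config, gt)
    ct = simulate_qpcr(config, gt)

    paths = {
        "genome": outdir / "genome.fa",
        "known_gtf": outdir / "known.gtf",
        "candidate_gtf": outdir / "candidates.gtf",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "terms": outdir / "terms.tsv",
        "qpcr_ct": outdir / "qpcr_ct.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    _write_fasta(genome, paths["genome"])
    write_gtf(known, paths["known_gtf"])
    write_gtf(candidates, paths["candidate_gtf"])
    counts.to_csv(paths["counts"], sep="\t")
    samples_df = pd.DataFrame({
        "sample": config.sample_names,
        "group": [groups[s] for s in config.sample_names],
        "library_size": [int(libs[s]) for s in config.sample_names],
    })
    samples_df.to_csv(paths["samples"], sep="\t", index=False)
    terms.to_csv(paths["terms"], sep="\t", index=False)
    ct.to_csv(paths["qpcr_ct"], sep="\t", float_format="%.4f")
    gt.to_json(paths["ground_truth"])
    return paths
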