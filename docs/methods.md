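# Methods

`lnclact` implements the downstream analysis that typically follows bulk
RNA-seq assembly in a two-condition lncRNA study: candidate lncRNA
identification from assembled transcript models, FPKM quantification,
exact-test differential expression between a 2-sample and a 3-sample
group, cis/trans target-gene prediction, hypergeometric term enrichment,
regulatory-network export, and 2^-ddCt qPCR concordance. The reference
design it emulates is a mammary-gland comparison of peak lactation (LP,
n=2) against the dry period (DP, n=3). Everything runs from plain-text
inputs (GTF, FASTA, TSV); a seeded generator produces a complete synthetic
input bundle with planted ground truth so that every stage's recovery is
testable without any downloads.

## Coordinates and annotation model

All coordinates are GTF-style: 1-based, closed intervals. Exon overlap is
defined at single-base resolution on exons (introns do not count); gene
"spans" run from the first to the last exonic base of any member
transcript. Strand must be `+` or `-`; a `.` strand is rejected at parse
time because antisense classification and ORF scanning are strand
operations and silently guessing would corrupt both. The interval index
(an interval tree per chromosome) uses half-open intervals internally and
never exposes them.

## Identification cascade

A candidate transcript survives iff it

1. has >= 2 exons;
2. has spliced length strictly greater than 200 nt (a 200-nt transcript
   is removed);
3. reaches FPKM >= 0.5 (inclusive) in at least one sample — the
   max-over-samples reading keeps stage-specific transcripts, which are
   the object of study;
4. shares no exonic base with any known transcript, on either strand;
5. shows no coding potential.

All five rules are evaluated for every candidate (no short-circuit), so
each verdict records the complete list of failed rules for auditing; the
pass/fail outcome is order-independent by construction.

Coding potential is scored by the longest ATG-initiated, stop-terminated
open reading frame over the three forward frames of the strand-resolved
spliced sequence, with a 300 nt (100 codon) threshold — the conventional
lncRNA heuristic. Codons containing N neither start, extend nor close an
ORF. An intersection mode accepts external per-tool verdict tables
(CNCI/CPC/Pfam-style): a transcript is noncoding only if the ORF rule and
every external tool agree; any single "coding" call removes it.

Survivors are classified as **antisense** when they overlap a known
gene's span (exonic or intronic overlap) on the opposite strand, else
**lincRNA**. Note the asymmetry with rule 4: rule 4 is strand-agnostic
and exon-restricted, so the antisense class that can actually survive the
cascade is intronic-antisense (plus span-overlapping transcripts that
avoid known exons). This is the only reading under which both the
exon-overlap removal rule and a non-empty antisense class can coexist.

## Expression and differential expression

FPKM[f,s] = counts[f,s] * 1e9 / (length[f] * library_size[s]), with plain
spliced length (no effective-length correction). Library summaries report
mapping percentages at two decimals and group read sums in millions.

DE uses the exact test for negative-binomial counts with a common
dispersion, the NB parameterized as Var = mu + phi mu^2:

* Counts are equalized to the geometric-mean library size and rounded
  (no TMM; the normalization hook is a config point).
* Conditional on the total S of a feature, the null law of the LP-group
  sum is p-free and depends only on phi and the group sizes:
  P(a | S) = C-style ratios of Gamma functions with per-group sizes
  n_g/phi; phi = 0 reduces to Binomial(S, n_LP/n).
* The two-sided p-value sums the probabilities of all splits no more
  probable than the observed one (not the doubling rule), capped at 1;
  S = 0 gives p = 1.
* phi maximizes the conditional (on per-group totals) log-likelihood
  summed over features, by bounded search on [0, 10]; a boundary optimum
  returns exactly 0. An optional trim fraction (pipeline default 0.1)
  drops the most-dispersed features (ranked by their individual
  conditional-ML phi on a grid) before pooling. The trim exists because a
  small set of features with genuine extra-Poisson biological variation —
  the synthetic trans hubs here, tagwise outliers in real data — can
  otherwise drag the pooled estimate several-fold above the bulk value.
  Common-only (no tagwise/trended) dispersion is a documented limitation
  of n = 5 designs.
* A feature is differentially expressed iff |log2(LP/DP)| >= 1 and raw
  p < 0.05; fold changes come from normalized group means with a 0.5
  pseudo-count used only when a group mean is zero and never in the test.
  BH-adjusted p-values are reported alongside for the reader but play no
  part in the calls.

At n = 5, the exact test with the sum-of-less-probable-outcomes rule is
approximately calibrated: the measured type-I error at alpha = 0.05 over
10,000 null features sits near 0.047–0.054 (slightly discrete-test
dependent), inside the [0.042, 0.058] band expected of a calibrated test.

## Target prediction

**Cis**: genes whose span intersects the lncRNA's span padded by 100 kb
on both sides, same chromosome, strand-agnostic, boundary-inclusive
(a gap of exactly 100,000 bp is reported). Distances are span gaps (0 on
overlap), signed relative to the lncRNA's strand.

**Trans**: all DEL x DEG pairs are screened with Pearson correlation
across the five samples; a pair is kept iff |r| > 0.95 (strict) and
p < 0.05, where p = 2 P(T_{n-2} > |r| sqrt((n-2)/(1-r^2))). By default r
is computed on log2(FPKM + 0.1). This is a deliberate choice: with five
samples a raw-scale Pearson coefficient is dominated by the single most
highly expressed sample, which both destroys power and inflates the null
pass rate of the |r| > 0.95 filter severalfold; on the log scale the null
rate matches the nominal ~1.3% for this threshold. Raw-scale correlation
is available via a flag. Zero-variance vectors are skipped with a logged
warning rather than an error — with n = 5 they occur legitimately.

## Enrichment

One hypergeometric upper-tail test per term, computed by log-space
summation (log-Gamma binomials + logsumexp); background = all genes in
the supplied term mapping. A term is flagged significant when the overlap
k is strictly greater than 5 AND raw p < 0.05; BH-adjusted values are
reported alongside, and both thresholds are per-run parameters because
conventions differ between GO-style (adjusted) and pathway-style (raw)
reporting. The rich factor k/K is exported for bubble plots. GO-style
and KEGG-style mappings are treated identically — both reduce to
over-representation tests. In the pipeline the cis and trans target sets
are tested as separate queries: positional neighbors and co-expression
partners are different hypotheses, and pooling them (the cis set spans
most of a compact genome) would dilute any signal.

## Network and qPCR

The regulatory network is a bipartite multigraph lncRNA -> gene; nodes
carry kind and DE direction, edges carry mode (cis/trans) and weight
(r for trans, negative distance for cis). Cis and trans evidence between
the same pair stays as two edges — they are distinct claims. Exports:
SIF + node attributes, a round-trippable edge TSV, and GraphML, all
byte-deterministic.

2^-ddCt: dCt = Ct_target − mean(Ct_HMBS, Ct_YWHAZ) (arithmetic mean of
reference Cts, equivalent to geometric-mean normalization of expression);
the calibrator is the mean DP dCt, since DP is the comparison baseline
throughout; amplification efficiency is fixed at 2. Fold changes are
invariant to per-sample global Ct shifts and to swapping the two
reference genes. Concordance against RNA-seq is the fraction of features
whose log2 fold changes agree in sign.

## Synthetic data generator

The generator is first-class, tested code. Defaults mirror the emulated
study design: 2 chromosomes of 1 Mb; 100 coding genes (2–10 exons,
planted ORFs >= 300 nt); 40 true lncRNAs (30 lincRNA, 10
intronic-antisense on the opposite strand of host genes), spliced lengths
mostly 200–2,500 nt with ORFs < 300 nt; 10 decoys per failure mode
(single-exon, length <= 200 with one exactly at 200, FPKM below 0.5,
exon overlap with known models on both strands, and long-ORF coding
decoys) — each decoy violates exactly one rule; 2-vs-3 group sizes;
library sizes 18–22 million; NB dispersion phi = 0.1; planted DE at
|log2FC| = 2 (10 lncRNAs, 20 genes, split up/down); qPCR noise 0.15 Ct.
Each stage draws from its own RNG stream keyed by (master seed, stage
name), so adding a stage never perturbs earlier draws; identical seeds
give byte-identical bundles.

Planted trans pairs use a latent-factor construction: two hub lncRNAs
each share a per-sample log-normal factor (sd 3 log2 units) with eight
target genes, plus a hub-level group effect, so planted pairs correlate
near 1 on the log scale while cross-hub pairs stay near the null.
The deliberately extreme latent spread is what makes |r| > 0.95
recoverable at all at n = 5 — the sampling spread of r at five points is
wide (Fisher sd ~0.71 in z), so planted-pair recall is ~60–100%
depending on seed, while precision against planted truth stays at ~1.0.
A consequence worth naming: any two same-direction DE features in a
2-vs-3 design correlate strongly through the group-mean pattern alone,
so the pipeline's full DEL x DEG screen legitimately reports more
interactions than the planted ones, exactly as real studies report
thousands of trans interactions. Precision is therefore measured on the
planted trans block, where ground truth is defined.

The term annotation assigns each coding gene 1–5 of 20 terms; the planted
enriched term covers 90% of the trans-target genes and 5% of the rest.
The zero-noise qPCR table reproduces planted fold changes exactly
(2^-ddCt = 2 for log2FC = 1), which pins the whole ddCt arithmetic.

What the generator does **not** emulate: read-level artifacts, positional
or GC bias, batch effects, assembly fragmentation, tagwise dispersion
spread, or realistic gene density (the synthetic genome is ~50x denser
than a mammalian one, which is why cis windows catch dozens of genes and
pipeline-level enrichment of the cis set is expectedly null). Passing the
planted-truth suites therefore demonstrates the correctness of the
implemented rules and statistics, not the biological error rates to
expect on real data.

## Numerical choices

* All probability work is in log space (gammaln, logsumexp); exact-test
  ties use a 1e-10 relative guard so float rounding cannot split equal-
  probability outcomes.
* The exact test and the dispersion likelihood round equalized counts to
  integers; with near-equal library sizes the perturbation is < 1 count.
* Pearson r is clamped to [-1, 1]; |r| within 1e-12 of 1 returns p = 0.
* Deterministic orderings everywhere (sorted ids, stable sorts, fixed
  float formats) make every output file byte-reproducible; the run
  manifest records config and input hashes and carries no timestamp.
* Degenerate inputs: all-zero count matrices, empty DEG sets, empty
  queries, and zero-lncRNA bundles all produce empty-but-valid outputs
  rather than errors.

## Problem sizes used in the checks

The shipped test suite and `scripts/acceptance.py` run at the default
generator scale (190 transcripts x 5 samples), with 10,000 features for
type-I calibration, 2,000 for dispersion recovery, all 2-vs-3 splits with
totals <= 30 for exact-test enumeration, and 400 random configurations
(N <= 50) for the hypergeometric oracle — sizes chosen so that the whole
battery completes in well under a minute while keeping Monte-Carlo
standard errors a few times smaller than the margins being asserted.
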