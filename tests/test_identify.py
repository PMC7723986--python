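"""ORF scanning, coding-potential calls, the filter cascade and its audit
trail, lncRNA classification and set summaries."""

import numpy as np
import pandas as pd
import pytest

from lnclact.annotation import Annotation, Exon, Transcript
from lnclact.identify import (
    FilterConfig,
    FilterVerdict,
    classify_lncrna,
    longest_orf,
    run_filter_cascade,
    score_coding_potential,
    summarize_lncrna_set,
)


def brute_force_orf(seq: str) -> int:
    """Exhaustive scan of every ATG: independent oracle for longest_orf."""
    seq = seq.upper()
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for i in range(len(seq) - 2):
        if seq[i:i + 3] != "ATG":
            continue
        j = i
        while j + 3 <= len(seq):
            codon = seq[j:j + 3]
            if "N" in codon:
                break
            if codon in stops:
                best = max(best, j + 3 - i)
                break
            j += 3
    return best


class TestLongestOrf:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGAAATAG", 9),                  # single complete ORF
        ("CCCCCC", 0),                     # no start codon
        ("ATGAAA", 0),                     # start but no stop
        ("AATGAAATAGG", 9),                # frame 1
        ("ATGTAA", 6),                     # minimal ORF
        ("ATGNNATAG", 0),                  # N voids the open ORF
        ("ATGATGAAATAA", 12),              # nested starts: earliest wins
    ])
    def test_known_cases(self, seq, expected):
        assert longest_orf(seq) == expected

    def test_matches_exhaustive_scan_on_random_sequences(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGTN"), size=1000,
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            assert longest_orf(seq) == brute_force_orf(seq)


class TestCodingPotential:
    def _tx(self):
        return Transcript("t1", "g1", "chr1", "+", [Exon("chr1", 1, 400)])

    def test_orf_threshold_is_inclusive(self):
        cfg = FilterConfig()
        # 299-nt ORFs are impossible (not a codon multiple); use 297 vs 300
        below = "ATG" + "GCA" * 97 + "TAA"          # 297 nt
        at = "ATG" + "GCA" * 98 + "TAA"             # 300 nt
        assert score_coding_potential(self._tx(), below, cfg) == "noncoding"
        assert score_coding_potential(self._tx(), at, cfg) == "coding"

    def test_intersection_mode_any_coding_call_wins(self):
        cfg = FilterConfig(evidence_mode="intersection_with_external")
        seq = "ATGTAA" + "C" * 100                   # ORF well below threshold
        ext = {"toolA": {"t1": "noncoding"}, "toolB": {"t1": "coding"}}
        assert score_coding_potential(self._tx(), seq, cfg, ext) == "coding"
        ext_all_nc = {"toolA": {"t1": "noncoding"}, "toolB": {"t1": "noncoding"}}
        assert score_coding_potential(self._tx(), seq, cfg, ext_all_nc) == "noncoding"

    def test_external_verdict_missing_transcript_errors(self):
        cfg = FilterConfig(evidence_mode="intersection_with_external")
        with pytest.raises(KeyError, match="t1"):
            score_coding_potential(self._tx(), "ATGTAA", cfg, {"toolA": {}})


def _mini_setup():
    """A tiny hand-built scene: one known gene plus candidates exercising
    each structural rule (the all-C genome contains no ATG, so the
    coding-potential rule never fires here)."""
    genome = {"chr1": "C" * 20000}
    known = Annotation([
        Transcript("KG1.t1", "KG1", "chr1", "+",
                   [Exon("chr1", 1000, 1400), Exon("chr1", 1800, 2200)],
                   "known_coding"),
    ])

    candidates = Annotation()
    # passes everything: 2 exons, 500 nt, intergenic
    candidates.add_transcript(Transcript(
        "ok", "ok", "chr1", "+",
        [Exon("chr1", 5000, 5249), Exon("chr1", 5500, 5749)]))
    # single exon, long and expressed
    candidates.add_transcript(Transcript(
        "se", "se", "chr1", "+", [Exon("chr1", 8000, 12999)]))
    # exactly 200 nt spliced (boundary: removed)
    candidates.add_transcript(Transcript(
        "short", "short", "chr1", "-",
        [Exon("chr1", 14000, 14099), Exon("chr1", 14300, 14399)]))
    # overlaps the known gene's exon by one base, opposite strand
    candidates.add_transcript(Transcript(
        "ovl", "ovl", "chr1", "-",
        [Exon("chr1", 2200, 2400), Exon("chr1", 2600, 2800)]))
    fpkm = pd.DataFrame(
        {"s1": [1.0, 10.0, 5.0, 2.0], "s2": [0.2, 9.0, 4.0, 1.0]},
        index=["ok", "se", "short", "ovl"],
    )
    return candidates, known, fpkm, genome


class TestFilterCascade:
    def test_hand_built_verdicts(self):
        candidates, known, fpkm, genome = _mini_setup()
        verdicts = {v.transcript_id: v
                    for v in run_filter_cascade(candidates, known, fpkm, genome)}
        assert verdicts["ok"].passed and verdicts["ok"].failed_rules == []
        assert verdicts["se"].failed_rules == ["single_exon"]
        assert verdicts["short"].failed_rules == ["too_short"]
        assert verdicts["ovl"].failed_rules == ["annotation_overlap"]

    def test_fpkm_rule_uses_max_over_samples(self):
        candidates, known, fpkm, genome = _mini_setup()
        fpkm.loc["ok"] = [0.5, 0.01]   # max exactly at the inclusive threshold
        v = {x.transcript_id: x
             for x in run_filter_cascade(candidates, known, fpkm, genome)}
        assert "low_fpkm" not in v["ok"].failed_rules
        fpkm.loc["ok"] = [0.49, 0.01]
        v = {x.transcript_id: x
             for x in run_filter_cascade(candidates, known, fpkm, genome)}
        assert "low_fpkm" in v["ok"].failed_rules

    def test_missing_fpkm_row_names_transcript(self):
        candidates, known, fpkm, genome = _mini_setup()
        with pytest.raises(KeyError, match="ok"):
            run_filter_cascade(candidates, known, fpkm.drop(index="ok"), genome)

    def test_recovers_planted_truth_exactly(self, bundle):
        verdicts = run_filter_cascade(bundle["candidates"], bundle["known"],
                                      bundle["fpkm"], bundle["genome"])
        survivors = {v.transcript_id for v in verdicts if v.passed}
        assert survivors == set(bundle["gt"].true_lncrnas)
        for v in verdicts:
            if not v.passed:
                assert v.failed_rules == [bundle["gt"].decoys[v.transcript_id]]
            else:
                assert v.lnc_class == bundle["gt"].true_lncrnas[v.transcript_id]

    def test_cascade_is_idempotent(self, bundle):
        verdicts = run_filter_cascade(bundle["candidates"], bundle["known"],
                                      bundle["fpkm"], bundle["genome"])
        survivors = sorted(v.transcript_id for v in verdicts if v.passed)
        again = Annotation([bundle["candidates"].transcripts[t] for t in survivors])
        verdicts2 = run_filter_cascade(again, bundle["known"], bundle["fpkm"],
                                       bundle["genome"])
        assert sorted(v.transcript_id for v in verdicts2 if v.passed) == survivors

    def test_survivors_plus_failures_partition_candidates(self, bundle):
        verdicts = run_filter_cascade(bundle["candidates"], bundle["known"],
                                      bundle["fpkm"], bundle["genome"])
        n_pass = sum(v.passed for v in verdicts)
        n_fail = sum(bool(v.failed_rules) for v in verdicts)
        assert n_pass + n_fail == len(verdicts)


class TestClassification:
    def test_opposite_strand_inside_gene_span_is_antisense(self):
        known = Annotation([Transcript(
            "g.t1", "g", "chr1", "+",
            [Exon("chr1", 1000, 1200), Exon("chr1", 5000, 5200)])])
        inside = Transcript("x", "x", "chr1", "-", [Exon("chr1", 2000, 2300)])
        far = Transcript("y", "y", "chr1", "-", [Exon("chr1", 55000, 55300)])
        same = Transcript("z", "z", "chr1", "+", [Exon("chr1", 2000, 2300)])
        assert classify_lncrna(inside, known) == "antisense"
        assert classify_lncrna(far, known) == "lincRNA"
        assert classify_lncrna(same, known) == "lincRNA"


class TestSummary:
    def _verdict(self, tid, cls):
        return FilterVerdict(tid, True, [], 120, cls)

    def test_reported_class_percentages(self):
        # 1374 lincRNA + 225 antisense -> 85.9% / 14.1%
        verdicts = [self._verdict(f"l{i}", "lincRNA") for i in range(1374)]
        verdicts += [self._verdict(f"a{i}", "antisense") for i in range(225)]
        transcripts = {
            v.transcript_id: Transcript(v.transcript_id, v.transcript_id,
                                        "chr1", "+", [Exon("chr1", 1, 500)])
            for v in verdicts
        }
        s = summarize_lncrna_set(verdicts, transcripts)
        assert s["class_pct"] == {"antisense": 14.1, "lincRNA": 85.9}

    def test_single_survivor_is_hundred_percent(self):
        v = [self._verdict("a", "lincRNA")]
        tx = {"a": Transcript("a", "a", "chr1", "+", [Exon("chr1", 1, 300)])}
        s = summarize_lncrna_set(v, tx)
        assert s["class_pct"] == {"lincRNA": 100.0}
        assert s["mean_exon_number"] == 1.0

    def test_histograms_match_hand_count(self):
        lengths = [300, 1999, 2000, 2001, 4100, 250, 700, 2500, 900, 3999]
        verdicts, transcripts = [], {}
        for i, ln in enumerate(lengths):
            tid = f"t{i}"
            verdicts.append(FilterVerdict(tid, True, [], 60 + i, "lincRNA"))
            transcripts[tid] = Transcript(
                tid, tid, "chr1", "+",
                [Exon("chr1", 1, 100), Exon("chr1", 200, 200 + ln - 101)])
            assert transcripts[tid].spliced_length == ln
        s = summarize_lncrna_set(verdicts, transcripts)
        assert s["length_hist"] == {"1-2000": 6, "2001-4000": 3, "4001-6000": 1}
        assert s["exon_count_hist"] == {2: 10}
        assert s["mean_exon_number"] == 2.0
        # ORF lengths 60..69 all land in the 51-100 bin
        assert s["orf_length_hist"] == {"51-100": 10}
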