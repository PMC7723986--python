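"""End-to-end orchestration: identify -> quantify/DE -> cis/trans targets ->
enrichment -> network -> qPCR concordance.

A :class:`PipelineConfig` (YAML on disk, plain nested keys) carries every
threshold with the pipeline's canonical defaults, the input/output paths
and per-stage on/off switches.  ``run_pipeline`` executes the enabled
stages in order, writes one output file set per stage, and finishes with a
manifest (config hash, input checksums, per-stage row counts, warnings,
package version).  Re-running on identical inputs yields byte-identical
outputs; the manifest carries no timestamp for that reason.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import Annotation, read_gtf, write_gtf
from .enrichment import enrich
from .expression import (ExpressionMatrix, call_differential, compute_fpkm,
                         estimate_common_dispersion)
from .identify import FilterConfig, run_filter_cascade, summarize_lncrna_set
from .network import build_network, export_network
from .qpcr import CtTable, concordance_report, ddct_fold_change
from .simulate import SimulationConfig, write_bundle
from .targets import find_cis_targets, find_trans_targets, overlap_cis_trans

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "simulate_command"]

logger = logging.getLogger(__name__)

STAGES = ("identify", "de", "targets", "enrich", "network", "qpcr")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    bundle_dir: str = "."
    out_dir: str = "results"
    # identification thresholds
    min_exons: int = 2
    min_length_nt: int = 200
    min_fpkm: float = 0.5
    coding_orf_threshold_nt: int = 300
    evidence_mode: str = "orf_only"
    # differential expression
    de_lfc_threshold: float = 1.0
    de_alpha: float = 0.05
    dispersion_trim: float = 0.1   # robust common-dispersion trimming fraction
    # targets
    cis_window: int = 100_000
    trans_r_threshold: float = 0.95
    trans_alpha: float = 0.05
    trans_log_transform: bool = True
    # enrichment
    enrich_min_gene_count: int = 5
    enrich_alpha: float = 0.05
    # misc
    seed: int = 7
    gene_whitelist: list[str] | None = None
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    def filter_config(self) -> FilterConfig:
        return FilterConfig(self.min_exons, self.min_length_nt, self.min_fpkm,
                            self.coding_orf_threshold_nt, self.evidence_mode)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_fasta(path) -> dict[str, str]:
    genome: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            else:
                parts.append(line)
    if name is not None:
        genome[name] = "".join(parts)
    return genome


def simulate_command(sim_config: SimulationConfig, outdir) -> dict[str, Path]:
    """Write the full synthetic input bundle (see :func:`write_bundle`)."""
    return write_bundle(sim_config, outdir)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order and return the manifest dict.

    Internal products needed by an enabled downstream stage are computed
    even when their own stage is switched off; files are written only for
    enabled stages.  Any stage error aborts the run as a StageError naming
    the stage.
    """
    bundle = Path(config.bundle_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    inputs = {
        "known_gtf": bundle / "known.gtf",
        "candidate_gtf": bundle / "candidates.gtf",
        "genome": bundle / "genome.fa",
        "counts": bundle / "counts.tsv",
        "samples": bundle / "samples.tsv",
        "terms": bundle / "terms.tsv",
    }
    for name, p in inputs.items():
        if not p.exists():
            raise FileNotFoundError(f"missing input {name}: {p}")
    qpcr_path = bundle / "qpcr_ct.tsv"

    manifest: dict = {
        "tool": "lnclact",
        "version": __version__,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(
                {k: v for k, v in asdict(config).items()
                 if k not in ("bundle_dir", "out_dir")},  # paths excluded: hash covers analysis parameters only
                sort_keys=True,
            ).encode()
        ).hexdigest(),
        "inputs": {k: _sha256(p) for k, p in sorted(inputs.items())},
        "stages": {},
        "outputs": [],
        "warnings": 0,
    }
    if qpcr_path.exists():
        manifest["inputs"]["qpcr_ct"] = _sha256(qpcr_path)

    enabled = {s for s in STAGES if config.stages.get(s, False)}
    if not enabled:
        _write_manifest(manifest, out)
        return manifest

    # --- shared inputs ------------------------------------------------------
    known = read_gtf(inputs["known_gtf"])
    candidates = read_gtf(inputs["candidate_gtf"])
    genome = _read_fasta(inputs["genome"])
    counts = pd.read_csv(inputs["counts"], sep="\t", index_col=0)
    samples = pd.read_csv(inputs["samples"], sep="\t")
    groups = dict(zip(samples["sample"], samples["group"]))
    libs = pd.Series(samples["library_size"].to_numpy(dtype=float),
                     index=samples["sample"])
    lengths = pd.Series({tid: t.spliced_length
                         for tid, t in candidates.transcripts.items()})
    fpkm = compute_fpkm(counts, lengths, libs)

    def emit(path: Path) -> Path:
        manifest["outputs"].append(path.name)
        return path

    # --- identify -----------------------------------------------------------
    try:
        verdicts = run_filter_cascade(candidates, known, fpkm, genome,
                                      config.filter_config())
        survivors = [v.transcript_id for v in verdicts if v.passed]
        summary = summarize_lncrna_set(verdicts, candidates.transcripts)
        if "identify" in enabled:
            vdf = pd.DataFrame(
                [(v.transcript_id, v.passed, ",".join(v.failed_rules),
                  v.orf_length_nt, v.lnc_class) for v in verdicts],
                columns=["transcript_id", "passed", "failed_rules",
                         "orf_length_nt", "class"],
            )
            vdf.to_csv(emit(out / "filter_verdicts.tsv"), sep="\t", index=False)
            lnc_ann = Annotation(
                [candidates.transcripts[t] for t in sorted(survivors)])
            write_gtf(lnc_ann, emit(out / "lncrna.gtf"))
            with open(emit(out / "lncrna_summary.json"), "w") as fh:
                json.dump(summary, fh, indent=1, sort_keys=True)
        manifest["stages"]["identify"] = {
            "candidates": len(verdicts),
            "survivors": len(survivors),
            **{f"class_{c}": n for c, n in summary["class_counts"].items()},
        }
    except Exception as exc:  # noqa: BLE001 - rethrown with stage name
        raise StageError("identify", exc) from exc

    # --- differential expression -------------------------------------------
    try:
        matrix = ExpressionMatrix(counts, groups, libs, fpkm)
        phi = estimate_common_dispersion(counts, groups, libs,
                                         trim=config.dispersion_trim)
        de = call_differential(matrix, phi=phi,
                               lfc_threshold=config.de_lfc_threshold,
                               alpha=config.de_alpha)
        de = de.set_index("feature_id", drop=False)
        known_tids = set(known.transcripts)
        del_ids = sorted(t for t in survivors
                         if t in de.index and de.loc[t, "significant"])
        deg_tids = sorted(t for t in known_tids
                          if t in de.index and de.loc[t, "significant"])
        if "de" in enabled:
            de_out = de.reset_index(drop=True)
            de_out.to_csv(emit(out / "de_results.tsv"), sep="\t", index=False,
                          float_format="%.6g")
        manifest["stages"]["de"] = {
            "n_del": len(del_ids),
            "n_deg": len(deg_tids),
            "del_up": int((de.loc[del_ids, "direction"] == "up").sum()),
            "del_down": int((de.loc[del_ids, "direction"] == "down").sum()),
            "deg_up": int((de.loc[deg_tids, "direction"] == "up").sum()),
            "deg_down": int((de.loc[deg_tids, "direction"] == "down").sum()),
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("de", exc) from exc

    tid_to_gene = {tid: t.gene_id for tid, t in known.transcripts.items()}

    # --- targets ------------------------------------------------------------
    try:
        del_transcripts = [candidates.transcripts[t] for t in del_ids]
        cis = find_cis_targets(del_transcripts, known, config.cis_window)
        deg_fpkm = fpkm.loc[deg_tids].rename(index=tid_to_gene)
        trans = find_trans_targets(fpkm.loc[del_ids], deg_fpkm,
                                   config.trans_r_threshold, config.trans_alpha,
                                   log_transform=config.trans_log_transform)
        both = overlap_cis_trans(cis, trans)
        if "targets" in enabled:
            pd.DataFrame(
                [(c.lncrna_id, c.gene_id, c.distance, c.side) for c in cis],
                columns=["lncrna_id", "gene_id", "distance", "side"],
            ).to_csv(emit(out / "cis_targets.tsv"), sep="\t", index=False)
            pd.DataFrame(
                [(t.lncrna_id, t.gene_id, t.r, t.p_value, t.sign) for t in trans],
                columns=["lncrna_id", "gene_id", "r", "p_value", "sign"],
            ).to_csv(emit(out / "trans_targets.tsv"), sep="\t", index=False,
                     float_format="%.6g")
            pd.DataFrame({"gene_id": sorted(both)}).to_csv(
                emit(out / "cis_trans_overlap.tsv"), sep="\t", index=False)
        manifest["stages"]["targets"] = {
            "n_cis": len(cis),
            "n_trans": len(trans),
            "trans_positive": sum(1 for t in trans if t.sign == "positive"),
            "trans_negative": sum(1 for t in trans if t.sign == "negative"),
            "cis_trans_overlap": len(both),
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("targets", exc) from exc

    # --- enrichment ---------------------------------------------------------
    try:
        terms = pd.read_csv(inputs["terms"], sep="\t")
        # cis and trans target sets are tested separately, mirroring the
        # usual split (positional neighbors vs co-expression partners)
        queries = {
            "cis": {c.gene_id for c in cis},
            "trans": {t.gene_id for t in trans},
        }
        enrich_counts = {}
        for mode, query in queries.items():
            results = enrich(query, terms,
                             min_gene_count=config.enrich_min_gene_count,
                             alpha=config.enrich_alpha)
            if "enrich" in enabled:
                pd.DataFrame(
                    [(r.term_id, r.term_name, r.background_size, r.term_size,
                      r.query_size, r.overlap, r.p_value, r.adjusted_p,
                      r.rich_factor, r.significant) for r in results],
                    columns=["term_id", "term_name", "background_size",
                             "term_size", "query_size", "overlap", "p_value",
                             "adjusted_p", "rich_factor", "significant"],
                ).to_csv(emit(out / f"enrichment_{mode}.tsv"), sep="\t",
                         index=False, float_format="%.6g")
            enrich_counts[f"{mode}_terms_tested"] = len(results)
            enrich_counts[f"{mode}_significant"] = \
                sum(1 for r in results if r.significant)
        manifest["stages"]["enrich"] = enrich_counts
    except StageError:
        raise
    except Exception as exc:
        raise StageError("enrich", exc) from exc

    # --- network ------------------------------------------------------------
    try:
        de_lnc_dir = {t: de.loc[t, "direction"] for t in del_ids}
        de_gene_dir = {tid_to_gene[t]: de.loc[t, "direction"] for t in deg_tids}
        whitelist = set(config.gene_whitelist) if config.gene_whitelist else None
        net = build_network(cis, trans, de_lnc_dir, de_gene_dir, whitelist)
        if "network" in enabled:
            for fmt in ("sif", "edge_tsv", "graphml"):
                for p in export_network(net, out / "network", fmt):
                    emit(Path(p))
        manifest["stages"]["network"] = {
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("network", exc) from exc

    # --- qPCR concordance ---------------------------------------------------
    if "qpcr" in enabled and qpcr_path.exists():
        try:
            ct = pd.read_csv(qpcr_path, sep="\t", index_col=0)
            table = CtTable(ct, groups)
            feats = [f for f in ct.index
                     if f not in table.reference_genes and f in de.index]
            qfc = {f: ddct_fold_change(table, f).log2_fold_change for f in feats}
            rfc = {f: float(de.loc[f, "log2fc"]) for f in feats}
            report, fraction = concordance_report(qfc, rfc, feats)
            report.to_csv(emit(out / "qpcr_concordance.tsv"), sep="\t",
                          index=False, float_format="%.6g")
            manifest["stages"]["qpcr"] = {
                "n_features": len(feats),
                "sign_concordance": round(fraction, 4) if feats else None,
            }
        except StageError:
            raise
        except Exception as exc:
            raise StageError("qpcr", exc) from exc

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    manifest["outputs"] = sorted(manifest["outputs"])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("wrote manifest with %d outputs", len(manifest["outputs"]))
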