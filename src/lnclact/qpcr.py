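"""Relative qPCR quantification by the 2^-ddCt method and RNA-seq concordance.

Expression of each target is normalized to the arithmetic mean of two
reference-gene Ct values (default HMBS and YWHAZ; equivalent to
geometric-mean normalization on the expression scale), calibrated against
the mean dCt of the dry-period (DP) group, and reported as
fold change = 2^-ddCt per lactation (LP) sample with a group-mean summary.
Amplification efficiency is fixed at 2 (100%).

Concordance against RNA-seq compares per-feature log2 fold changes and
reports the fraction of features whose signs agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CtTable", "ddct_fold_change", "concordance_report",
           "DEFAULT_REFERENCE_GENES"]

DEFAULT_REFERENCE_GENES = ("HMBS", "YWHAZ")


@dataclass
class CtTable:
    """Ct values (features x samples) with reference genes and group labels."""

    ct: pd.DataFrame
    groups: dict[str, str]                       # sample -> "LP" | "DP"
    reference_genes: tuple[str, str] = DEFAULT_REFERENCE_GENES

    def __post_init__(self) -> None:
        if (self.ct.to_numpy(dtype=float) <= 0).any():
            raise ValueError("Ct values must be > 0")
        for ref in self.reference_genes:
            if ref not in self.ct.index:
                raise ValueError(f"reference gene {ref!r} missing from Ct table")
            if self.ct.loc[ref].isna().any():
                raise ValueError(f"reference gene {ref!r} has missing Ct values")
        for s in self.ct.columns:
            if self.groups.get(s) not in ("LP", "DP"):
                raise ValueError(f"sample {s!r} lacks a valid group label")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.ct.columns if self.groups[s] == group]


@dataclass
class FoldChangeResult:
    feature_id: str
    per_lp_sample: dict[str, float] = field(default_factory=dict)
    fold_change: float = float("nan")   # mean 2^-ddCt over LP samples
    log2_fold_change: float = float("nan")


def ddct_fold_change(table: CtTable, target_id: str) -> FoldChangeResult:
    """2^-ddCt fold change of ``target_id`` in LP relative to the DP mean.

    dCt(sample) = Ct_target - mean(Ct_ref1, Ct_ref2);
    ddCt(sample) = dCt(sample) - mean over DP samples of dCt;
    fold change  = 2^-ddCt, summarized as the mean over LP samples.
    """
    if target_id not in table.ct.index:
        raise KeyError(f"target {target_id!r} not in Ct table")
    ref_mean = table.ct.loc[list(table.reference_genes)].mean(axis=0)
    dct = table.ct.loc[target_id] - ref_mean
    if dct.isna().any():
        raise ValueError(f"missing Ct for target {target_id!r}")
    calibrator = float(dct[table.samples_in("DP")].mean())
    ddct = dct - calibrator
    fc = np.power(2.0, -ddct)
    lp = table.samples_in("LP")
    mean_fc = float(fc[lp].mean())
    return FoldChangeResult(
        feature_id=target_id,
        per_lp_sample={s: float(fc[s]) for s in lp},
        fold_change=mean_fc,
        log2_fold_change=float(np.log2(mean_fc)),
    )


def concordance_report(
    qpcr_log2fc: dict[str, float] | pd.Series,
    rnaseq_log2fc: dict[str, float] | pd.Series,
    features: list[str],
) -> tuple[pd.DataFrame, float]:
    """Paired log2 fold changes with per-feature sign agreement.

    Returns the per-feature table and the overall fraction of features
    whose qPCR and RNA-seq log2 fold changes share a sign.
    """
    qpcr = pd.Series(qpcr_log2fc, dtype=float)
    rnaseq = pd.Series(rnaseq_log2fc, dtype=float)
    rows = []
    for f in features:
        if f not in qpcr.index or f not in rnaseq.index:
            raise KeyError(f"feature {f!r} missing from one of the inputs")
        agree = bool(np.sign(qpcr[f]) == np.sign(rnaseq[f]))
        rows.append((f, float(qpcr[f]), float(rnaseq[f]), agree))
    df = pd.DataFrame(rows, columns=["feature_id", "qpcr_log2fc",
                                     "rnaseq_log2fc", "sign_agreement"])
    fraction = float(df["sign_agreement"].mean()) if len(df) else float("nan")
    return df, fraction
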