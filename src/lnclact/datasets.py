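"""Bundled example data.

``example_library_qc`` returns the sequencing/mapping QC summary of a
five-library bovid mammary-gland RNA-seq design (two peak-lactation and
three dry-period libraries, 125 bp paired-end), the input shape expected
by :func:`lnclact.expression.summarize_libraries`.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["example_library_qc"]

_QC_ROWS = {
    # sample: (raw_reads, clean_reads, q30_pct, gc_pct, total_mapped, uniquely_mapped)
    "DP1": (184408224, 181065646, 96.50, 53.07, 156206414, 143152662),
    "DP2": (155782622, 152534698, 96.53, 53.23, 131660504, 120711885),
    "DP3": (162876662, 158253090, 96.35, 53.07, 132600127, 121998364),
    "LP1": (160155930, 156985398, 96.53, 53.17, 135755839, 122863727),
    "LP2": (139072986, 135208918, 96.35, 50.51, 115961807, 107999673),
}


def example_library_qc() -> tuple[pd.DataFrame, dict[str, str]]:
    """The example QC table and its sample -> group mapping."""
    df = pd.DataFrame.from_dict(
        _QC_ROWS,
        orient="index",
        columns=["raw_reads", "clean_reads", "q30_pct", "gc_pct",
                 "total_mapped", "uniquely_mapped"],
    )
    df.index.name = "sample"
    groups = {s: ("LP" if s.startswith("LP") else "DP") for s in df.index}
    return df, groups
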