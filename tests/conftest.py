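import pandas as pd
import pytest

from lnclact.expression import compute_fpkm
from lnclact.simulate import (
    SimulationConfig,
    generate_genome_and_annotation,
    generate_term_annotation,
    simulate_counts,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def bundle(default_config):
    """The default synthetic dataset (seed 7): genome, annotations, truth,
    counts, FPKM and term annotation, generated once per session."""
    genome, known, candidates, gt = generate_genome_and_annotation(default_config)
    counts, groups, libs = simulate_counts(default_config, gt)
    lengths = pd.Series({tid: t.spliced_length
                         for tid, t in candidates.transcripts.items()})
    fpkm = compute_fpkm(counts, lengths, libs)
    terms = generate_term_annotation(default_config, gt)
    return {
        "config": default_config,
        "genome": genome,
        "known": known,
        "candidates": candidates,
        "gt": gt,
        "counts": counts,
        "groups": groups,
        "libs": libs,
        "lengths": lengths,
        "fpkm": fpkm,
        "terms": terms,
    }
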