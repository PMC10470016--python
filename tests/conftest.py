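import numpy as np
import pandas as pd
import pytest

from cernet import SimulationConfig, TranscriptRecord, simulate_study


def make_record(tid="T1", chrom="chr1", strand="+", start=1000, end=2000,
                exons=None, biotype="lncRNA", known=True):
    if exons is None:
        mid = (start + end) // 2
        exons = ((start, mid - 50), (mid + 50, end))
    return TranscriptRecord(tid, chrom, strand, start, end, tuple(exons),
                            biotype, known)


@pytest.fixture(scope="session")
def small_study():
    """One small coherent synthetic experiment shared by read-only tests."""
    cfg = SimulationConfig(seed=42, n_mrna=50, n_lncrna=50, n_mirna=15,
                           n_planted_triads=4)
    return simulate_study(cfg)


@pytest.fixture
def toy_matrix():
    """Tiny hand-checkable expression matrix: 3 transcripts x 4 samples."""
    from cernet import ExpressionMatrix
    counts = pd.DataFrame(
        {"A1": [10, 10, 0], "A2": [20, 20, 1], "C1": [10, 40, 2], "C2": [12, 44, 3]},
        index=["t1", "t2", "t3"], dtype=float)
    lengths = pd.Series({"t1": 1000.0, "t2": 2000.0, "t3": 500.0})
    groups = {"A1": "A", "A2": "A", "C1": "C", "C2": "C"}
    return ExpressionMatrix(counts=counts, lengths=lengths, groups=groups)
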