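import numpy as np
import pytest

from herdscan.genoqc import GenotypeMatrix
from herdscan.seqdiversity import PileupTable


def make_table(counts, chrom="chr1", start_pos=1):
    """PileupTable from a list of 4-tuples at consecutive positions."""
    counts = np.asarray(counts, dtype=np.int64)
    n = len(counts)
    return PileupTable(
        np.full(n, chrom), np.arange(start_pos, start_pos + n, dtype=np.int64), counts
    )


def make_genotypes(calls, chrom=None, pos=None):
    """GenotypeMatrix from a samples x variants list of dosages (-1 missing)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_s, n_v = calls.shape
    if pos is None:
        pos = np.arange(1, n_v + 1) * 100
    if chrom is None:
        chrom = np.full(n_v, "1", dtype=object)
    return GenotypeMatrix(
        [f"s{i}" for i in range(n_s)],
        np.asarray(chrom, dtype=object),
        np.asarray(pos, dtype=np.int64),
        np.full(n_v, "A", dtype=object),
        np.full(n_v, "G", dtype=object),
        calls,
    )


@pytest.fixture(scope="session")
def small_pileup():
    """1 Mb genome with one planted 300-kb zero-het tract; fixed seed."""
    from herdscan.simdata import simulate_pileup_genome

    table, truth = simulate_pileup_genome(
        1_000_000, theta=0.002, epsilon=0.002, mean_depth=10,
        roh_spec=[(300_000, 600_000, 0.0)], seed=42,
    )
    return table, truth
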