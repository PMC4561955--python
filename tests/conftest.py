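import numpy as np
import pytest

from hybridexpr.core import AnalysisConfig, CountTable, GeneMeta, SAMPLES


def make_table(rows, gene_ids=None, library_sizes=None, sample_labels=SAMPLES):
    """Build a CountTable from a list of per-gene count rows."""
    rows = np.asarray(rows, dtype=np.int64)
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(rows.shape[0])]
    ls = None
    if library_sizes is not None:
        ls = np.asarray(library_sizes, dtype=np.int64)
    return CountTable(gene_ids, rows, list(sample_labels), ls)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def tiny_counts():
    return make_table(
        [
            [10, 20, 15, 15],
            [0, 0, 0, 0],
            [100, 100, 100, 100],
        ]
    )


@pytest.fixture
def tiny_meta(tiny_counts):
    return {
        gid: GeneMeta(gid, 1000, frozenset({"GO:0000001"}))
        for gid in tiny_counts.gene_ids
    }
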