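import numpy as np
import pandas as pd
import pytest

from serialevo import popsim


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def ltr_library():
    return popsim.synthetic_ltr_library(seed=7)


@pytest.fixture
def two_lineage_config():
    """Minimal deterministic competition: one neutral, one test lineage."""
    return popsim.SimConfig(
        n_neutral_barcodes=1,
        n_test_barcodes=1,
        unbarcoded_fraction=0.0,
        n_transfers=4,
        generations_per_transfer=8.0,
        n_replicates=1,
        bottleneck_size=1000,
        deterministic=True,
    )


@pytest.fixture(scope="session")
def toy_gff3():
    """Two genes on opposite strands plus a tRNA, on a 10 kb toy chromosome."""
    return "\n".join(
        [
            "##gff-version 3",
            "chrT\ttoy\tgene\t2001\t3000\t.\t+\t.\tID=gene1;Name=GENA",
            "chrT\ttoy\tgene\t6001\t7000\t.\t-\t.\tID=gene2;Name=GENB",
            "chrT\ttoy\ttRNA_gene\t9001\t9072\t.\t+\t.\tID=trna1;Name=tT(AGU)",
        ]
    )


def make_counts(count_matrix, barcodes=None, replicate=0):
    """Tidy count table from a barcode x timepoint matrix."""
    arr = np.asarray(count_matrix)
    if barcodes is None:
        barcodes = [f"bc{i}" for i in range(arr.shape[0])]
    rows = [
        (b, replicate, t, int(arr[i, t]))
        for i, b in enumerate(barcodes)
        for t in range(arr.shape[1])
    ]
    return pd.DataFrame(rows, columns=["barcode", "replicate", "timepoint", "count"])
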