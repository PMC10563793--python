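import numpy as np
import pandas as pd
import pytest

from duplicability import simulate


def make_gene_table(rows):
    """rows: (gene_id, chromosome, order_index, intron_count, segment_id)."""
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chromosome", "order_index", "intron_count", "segment_id"],
    )


def make_pairs(rows):
    """rows: (gene_a, gene_b, duplication_node)."""
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "duplication_node"])


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate.simulate_study(small_config)


@pytest.fixture
def two_segment_genes():
    """Two chromosomes, 30 genes each; first 15 of each in a segment."""
    rows = []
    for ci, chrom in enumerate(["chr1", "chr2"]):
        for pos in range(30):
            seg = f"s{ci}" if pos < 15 else None
            rows.append((f"{chrom}_g{pos}", chrom, pos, 5, seg))
    return make_gene_table(rows)
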