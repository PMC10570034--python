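import numpy as np
import pandas as pd
import pytest

from gbmeth import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim():
    """Full-size simulated dataset at the default study conditions (seed 1)."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=7, n_chrom=1, chrom_len=30_000, n_genes=12,
        exons_per_gene=(2, 4), cds_len=(300, 900), gene_gap=(200, 800),
        te_fraction=0.1, spike_len=2_000, samples_per_dataset=3,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    """A tiny dataset for pipeline/CLI round trips."""
    return simulate_dataset(small_config)


def records_frame(rows):
    """Build a cytosine-record DataFrame from (chrom,pos,strand,context,m,u) tuples."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]
    )


@pytest.fixture
def toy_genome():
    # chr1: a 60 bp sequence with a single-exon ORF ATG AAA TAG at [10, 19)
    seq = list("ACGTACGTAC" + "ATGAAATAG" + "GCGCGCGCGCGCGCGCGCGCGCGCGCGCGCGCGCGCGCGCG")
    return {"chr1": "".join(seq)}
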