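import numpy as np
import pytest

from cerna.models import TranscriptModel
from cerna.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    """A dataset small enough for per-test simulation."""
    return SimConfig(n_mrna=20, n_lncrna=12, n_mirna=6, n_chrom=2,
                     n_de_mrna=6, n_de_lncrna=6, n_de_mirna=4,
                     n_planted_triplets=3, seed=7)


@pytest.fixture
def two_exon_gene():
    """Gene chr1:+ with exons [1000,1300) and [1700,2000)."""
    return TranscriptModel("g1", "gene_g1", "chr1", "+",
                           [(1000, 1300), (1700, 2000)], "mRNA")


def make_transcript(tid, chrom, strand, exons, biotype="other"):
    return TranscriptModel(tid, f"gene_{tid}", chrom, strand, list(exons), biotype)
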