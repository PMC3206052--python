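import numpy as np
import pytest

from segannot.fixtures import FixtureSpec, make_fixture
from segannot.gene_model import Genome, Transcript


@pytest.fixture(scope="session")
def fixture():
    """Default synthetic genome + gene set shared across tests."""
    return make_fixture(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def minus_fixture():
    return make_fixture(FixtureSpec(seed=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def simple_transcript(
    *,
    tid="tx1",
    gene="G1",
    chrom="chr1",
    strand="+",
    exons=((100, 200), (300, 500)),
    cds=(150, 450),
):
    exons = tuple(exons)
    return Transcript(
        id=tid,
        gene=gene,
        chrom=chrom,
        strand=strand,
        tx_start=exons[0][0],
        tx_end=exons[-1][1],
        cds_start=cds[0],
        cds_end=cds[1],
        exons=exons,
    )


@pytest.fixture()
def tiny_genome():
    """Single 9 bp chromosome carrying ATG AAA TGA."""
    return Genome({"chr1": "ATGAAATGA"})
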