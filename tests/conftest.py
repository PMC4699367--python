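import numpy as np
import pytest

from tukinetics.io_formats import ReadRecord, TranscriptModel


@pytest.fixture
def toy_gene():
    """Single-intron plus-strand gene: exon1 50 nt, intron 40 nt, exon2 50 nt."""
    return TranscriptModel(
        gene_id="toy1",
        chrom="chrT",
        strand="+",
        exons=[(100, 150), (190, 240)],
        tx_class="RP-intronic",
    )


@pytest.fixture
def toy_gene_minus():
    """Same structure on the minus strand (exon1 is the rightmost exon)."""
    return TranscriptModel(
        gene_id="toy2",
        chrom="chrT",
        strand="-",
        exons=[(100, 150), (190, 240)],
        tx_class="non-RP-intronic",
    )


def single_block_read(read_id, gene_id, start, length):
    return ReadRecord(read_id, gene_id, [(start, start + length)])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
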