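import numpy as np
import pytest

from autoclip.core_io import GenomicInterval, Peak, TranscriptModel


@pytest.fixture
def toy_model():
    """Single-gene model: utr5 [0,50), cds [50,350), utr3 [350,500), intron [500,600)."""
    return TranscriptModel(
        "GENE_A",
        "GENE_A.1",
        "+",
        utr5=[GenomicInterval("chr1", 0, 50)],
        cds=[GenomicInterval("chr1", 50, 350)],
        utr3=[GenomicInterval("chr1", 350, 500)],
        introns=[GenomicInterval("chr1", 500, 600)],
    )


def make_peak(start, end, rbp="RBP_A", chrom="chr1", score=1.0, dataset="ds1"):
    return Peak(GenomicInterval(chrom, start, end), rbp, dataset, score)


@pytest.fixture
def peak_factory():
    return make_peak


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
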