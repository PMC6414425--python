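import numpy as np
import pytest

from rloopkit.intervals import GeneRecord, GenomicInterval


@pytest.fixture
def simple_genes():
    """Three well-separated genes, one per class, mixed strands."""
    return [
        GeneRecord("gA", GenomicInterval("chr1", 5000, 8000, "+"), "pcg_repressed"),
        GeneRecord("gB", GenomicInterval("chr1", 20000, 26000, "-"), "active_top"),
        GeneRecord("gC", GenomicInterval("chr2", 5000, 9000, "+"), "inactive_bottom"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240811)
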