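import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from postdauer.regions import GeneModel, UpstreamRegion


@pytest.fixture
def toy_genome():
    # chrI: 60 bp with a + strand gene whose ATG starts at 30
    #       upstream [0,30) readable directly
    chrI = "ACGTACGTACGTACGTACGTACGTACGTAC" + "ATG" + "A" * 27
    return {"chrI": chrI, "chrP": "ACGTACGTACGTACGT"}


@pytest.fixture
def plus_gene():
    return GeneModel("gplus", "chrI", "+", 30, 300)


def region_from(seq, gene_id="g1"):
    """Wrap a bare sequence as an UpstreamRegion for scanning tests."""
    return UpstreamRegion(gene_id, "chrT", 0, len(seq), "+", seq,
                          truncated=len(seq) < 500)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
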