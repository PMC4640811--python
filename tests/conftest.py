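import numpy as np
import pytest

from retrosite._seq import random_dna
from retrosite.models import TargetGeneModel

# U2-style target gene fragment printed at model positions 39-59 in the
# diagnostic 21-mer tests
DIAGNOSTIC_21MER = "TCTGTTCTAATCAGTGTGAAA"


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def target_model(rng):
    """A 190-nt target model carrying the diagnostic 21-mer at 1-based
    positions 39-59 (so the post-insertion-site remainder starts with
    it)."""
    seq = random_dna(rng, 190)
    seq = seq[:38] + DIAGNOSTIC_21MER + seq[59:]
    return TargetGeneModel("U2like", seq)
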