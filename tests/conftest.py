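import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triad_bundle():
    """20 synthetic proteins: 5 each of 3/3, 2/3, 1/3, 0/3 planted motifs."""
    from triadminer import gen_triad_sequences

    return gen_triad_sequences(
        n=20, completeness_mix=(0.25, 0.25, 0.25, 0.25), length=400, seed=7
    )
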