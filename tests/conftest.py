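import numpy as np
import pytest

from rnarobo.descriptor import parse_descriptor


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_hairpin():
    """Minimal helix + loop motif: h1 s1 h1' with a two-base loop."""
    return parse_descriptor(
        """h1 s1 h1'
h1 0:0:0 N:N
s1 0:0 AA
"""
    )


@pytest.fixture
def five_singles():
    """Five single strands with known flexibilities (0, 2, 2, 0, 0)."""
    return parse_descriptor(
        """s1 s2 s3 s4 s5
s1 0:0 GGGG
s2 0:0 N**
s3 0:0 NN**
s4 0:0 NN
s5 0:0 CCCC
"""
    )
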