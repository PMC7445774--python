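import numpy as np
import pytest

from qtermseq.design import TerminatorDesign, sample_library


@pytest.fixture(scope="session")
def default_design():
    return TerminatorDesign()


@pytest.fixture(scope="session")
def toy_design():
    """Three degenerate positions (one S, two N): 32-sequence space,
    cheap to enumerate exhaustively."""
    return TerminatorDesign(stem_pattern_5arm="SNNGCC")


@pytest.fixture(scope="session")
def small_library(default_design):
    """Twenty variants drawn from the default design space."""
    return sample_library(default_design, 20, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
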