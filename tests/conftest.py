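import numpy as np
import pytest
import scipy.sparse as sp

from celltag_demux import MotifConfig, SimConfig, TagCountMatrix

TAG_A = "TGCTATAT"
TAG_B = "GTTGGCTA"


@pytest.fixture
def motif():
    return MotifConfig(flank5="ACCGGTTAAC", flank3="GAATTCGCGG", tag_length=8)


@pytest.fixture
def small_matrix():
    counts = np.array([[5, 0], [0, 3], [2, 2]])
    return TagCountMatrix(
        np.array(["c1", "c2", "c3"], dtype=object),
        np.array([TAG_A, TAG_B], dtype=object),
        sp.csr_matrix(counts),
    )


@pytest.fixture
def small_sim_config():
    """Down-scaled two-sample design for fast unit tests."""
    return SimConfig(samples=((TAG_A, 400), (TAG_B, 400)), seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
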