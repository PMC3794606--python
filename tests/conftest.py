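import numpy as np
import pytest

from p53recode import ConsensusModel

# The four probe sequences printed in full in the study's main text.
GGGCA_FULL = "GGGCATGCCCGGGCATGCCC"
GAACA_FULL = "GAACATGTTCGAACATGTTC"
CON_E = "GAGCATGTCC" * 2
CON_P = CON_E[:1] + "G" + CON_E[2:]  # A at full-site position 2 -> G


@pytest.fixture
def default_model():
    return ConsensusModel()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
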