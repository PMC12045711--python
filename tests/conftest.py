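import numpy as np
import pytest

from tigrkit import NucSeq, GuidePair, TIGRArrayModel, TIGRUnit
from tigrkit.fixtures import TA_LIKE_REPEAT_SET


@pytest.fixture
def ta_like():
    return TA_LIKE_REPEAT_SET


@pytest.fixture
def example_guide():
    return GuidePair("ACGUACGUA", "GGAUCCGGA")


@pytest.fixture
def example_genome():
    """Genome carrying the canonical zero-gap 18-mer site at offset 100."""
    rng = np.random.default_rng(20240901)
    left = "".join(rng.choice(list("ACGT"), size=100))
    right = "".join(rng.choice(list("ACGT"), size=100))
    seq = left + "ACGTACGTATCCGGATCC" + right
    # the flanks are random; regenerate deterministically if they ever collide
    return NucSeq("example", seq, "dna")


@pytest.fixture
def two_unit_model(ta_like):
    units = [TIGRUnit(1, "ACGTACGTA", "GGATCCGGA"), TIGRUnit(2, "AAACCCGGG", "TTTACGTAC")]
    return TIGRArrayModel(ta_like, units)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
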