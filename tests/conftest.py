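import numpy as np
import pytest

from solidsage import ReferenceSet, Transcript


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_seq(rng, length, gc=0.5):
    bases = np.array(list("ACGT"))
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(bases[rng.choice(4, size=length, p=p)])


@pytest.fixture
def two_part_refset():
    """A tiny hand-built plant + fungal reference with known tags."""
    plant = Transcript("plant1", "AA" + "CATG" + "C" * 23 + "A" * 30, "plant")
    plant2 = Transcript("plant2", "GG" + "CATG" + "G" * 23 + "A" * 30, "plant")
    fungal = Transcript("fungal1", "TT" + "CATG" + "T" * 11 + "G" * 12 + "A" * 30, "fungal")
    return ReferenceSet([plant, plant2, fungal])
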