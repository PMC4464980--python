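import numpy as np
import pytest

from amirnaforge import Precursor
from amirnaforge._seq import revcomp_rna


def random_rna(rng, length):
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, length)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def hairpin():
    """Deterministic synthetic hairpin: 10-nt flanks, 21-nt arms, 16-nt loop."""
    r = np.random.default_rng(7)
    mature = random_rna(r, 21)
    loop = random_rna(r, 16)
    flank5 = random_rna(r, 10)
    flank3 = random_rna(r, 10)
    seq = flank5 + mature + loop + revcomp_rna(mature) + flank3
    return Precursor(
        id="hp-test",
        sequence=seq,
        mature_span=(11, 31),
        star_span=(48, 68),
    )


@pytest.fixture
def amirna(rng):
    """A valid design-rule-conformant 21-nt amiRNA (U1, C19)."""
    seq = list(random_rna(rng, 21))
    seq[0], seq[18] = "U", "C"
    return "".join(seq)
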