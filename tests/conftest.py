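import random

import pytest

from clonesim.record import AnnotatedMolecule


def make_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def linear_molecule(rng):
    return AnnotatedMolecule.from_string(make_dna(rng, 120), id="lin")


@pytest.fixture
def circular_molecule(rng):
    return AnnotatedMolecule.from_string(make_dna(rng, 150), circular=True,
                                         id="circ")
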