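import numpy as np
import pytest

from halosolv import synthetic as syn


@pytest.fixture
def box60():
    return syn.BoxSpec(60.0)


@pytest.fixture
def ion_roster():
    return syn.SpeciesRoster.of(K=(200, "cation"), Cl=(200, "anion"))


@pytest.fixture
def solution_roster():
    return syn.SpeciesRoster.of(K=(200, "cation"), Cl=(200, "anion"),
                                water=(200, "water"))


@pytest.fixture
def rng():
    return np.random.default_rng(20210602)
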