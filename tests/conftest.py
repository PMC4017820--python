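import numpy as np
import pytest

from pedherit.pedigree import build_three_generation_pedigree, kinship_matrix


@pytest.fixture(scope="session")
def family_pedigree():
    """One eight-member three-generation family."""
    return build_three_generation_pedigree(1)


@pytest.fixture(scope="session")
def family_kinship(family_pedigree):
    return kinship_matrix(family_pedigree)


@pytest.fixture(scope="session")
def colony_study():
    """The synthetic 542-member colony emulation (built once per session)."""
    from pedherit.macaque import synthesize_macaque_study

    return synthesize_macaque_study(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
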