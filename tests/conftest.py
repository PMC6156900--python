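import numpy as np
import pytest

from famassoc.pedigree import Individual, Pedigree, sibship_pedigree
from famassoc.simulate import SimulationConfig


@pytest.fixture
def trio_pedigree() -> Pedigree:
    return Pedigree(
        [
            Individual("dad", "F1", sex="male"),
            Individual("mom", "F1", sex="female"),
            Individual("kid", "F1", father_id="dad", mother_id="mom"),
        ]
    )


@pytest.fixture
def half_sib_pedigree() -> Pedigree:
    """Shared father, unrelated mothers."""
    return Pedigree(
        [
            Individual("dad", "F1", sex="male"),
            Individual("mom1", "F1", sex="female"),
            Individual("mom2", "F1", sex="female"),
            Individual("h1", "F1", father_id="dad", mother_id="mom1"),
            Individual("h2", "F1", father_id="dad", mother_id="mom2"),
        ]
    )


@pytest.fixture
def two_sibships() -> Pedigree:
    return sibship_pedigree(2, 3)


@pytest.fixture
def small_config() -> SimulationConfig:
    """A desk-scale study: 40 sibships of 4, 120 markers, 8 causal."""
    return SimulationConfig(
        n_families=40,
        family_size=4,
        m_markers=120,
        m_causal=8,
        effect_delta=0.8,
        seed=42,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180917)
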