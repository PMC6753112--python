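import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from famh2.pedigree import Individual, Pedigree
from famh2.simulate import (GenotypeSpec, PedigreeSpec, TraitModel,
                            simulate_cohort, simulate_pedigrees)


@pytest.fixture(scope="session")
def default_panel() -> Pedigree:
    """The default-scale family panel (116 families, ~427 phenotyped)."""
    return simulate_pedigrees(PedigreeSpec(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """Small end-to-end cohort for integration-style tests."""
    return simulate_cohort(
        PedigreeSpec(n_families=40, target_total_individuals=150, seed=7),
        GenotypeSpec(n_snps=300), TraitModel(), seed=7)


@pytest.fixture
def nuclear3() -> Pedigree:
    """Two parents, three full-sib children."""
    return Pedigree([
        Individual("F1", "1", sex=1),
        Individual("F1", "2", sex=2),
        Individual("F1", "3", "1", "2", 1),
        Individual("F1", "4", "1", "2", 2),
        Individual("F1", "5", "1", "2", 1),
    ])


@pytest.fixture
def extended_family() -> Pedigree:
    """Three generations with half-sibs, avuncular and cousin pairs."""
    return Pedigree([
        Individual("F1", "gf", sex=1),
        Individual("F1", "gm", sex=2),
        Individual("F1", "p1", "gf", "gm", 1),
        Individual("F1", "p2", "gf", "gm", 2),
        Individual("F1", "s1", sex=2),       # spouse of p1
        Individual("F1", "s2", sex=1),       # spouse of p2
        Individual("F1", "c1", "p1", "s1", 1),
        Individual("F1", "c2", "p1", "s1", 2),
        Individual("F1", "c3", "s2", "p2", 1),
        Individual("F1", "h1", "p1", "gm2", 2),   # half-sib of c1/c2 (unknown mother)
    ])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
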