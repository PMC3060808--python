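import numpy as np
import pytest

from mechcodon.genetic_code import universal_code, vertebrate_mitochondrial_code
from mechcodon.model import mutational_codon_composition
from mechcodon.simulate import FixtureSpec, random_params, synthetic_empirical


@pytest.fixture(scope="session")
def universal():
    return universal_code()


@pytest.fixture(scope="session")
def vert_mito():
    return vertebrate_mitochondrial_code()


@pytest.fixture(scope="session")
def drawn_params(universal):
    """A representative seeded random parameter set."""
    return random_params(FixtureSpec(seed=3))


@pytest.fixture(scope="session")
def drawn_codon_freq(drawn_params, universal):
    return mutational_codon_composition(drawn_params.nuc, universal)


@pytest.fixture(scope="session")
def aa_fixture():
    """Noise-free amino-acid-level synthetic 1-PAM matrix with ground truth."""
    emp, truth = synthetic_empirical(FixtureSpec(seed=11, level="amino_acid"))
    return emp, truth


@pytest.fixture(scope="session")
def codon_fixture():
    """Noise-free codon-level synthetic 1-PAM matrix with ground truth."""
    emp, truth = synthetic_empirical(FixtureSpec(seed=11, level="codon"))
    return emp, truth


@pytest.fixture(scope="session")
def toy_reversible_4state():
    """A small reversible 4-state generator with unit total rate."""
    rng = np.random.default_rng(5)
    pi = rng.dirichlet(np.full(4, 8.0))
    S = np.zeros((4, 4))
    iu = np.triu_indices(4, 1)
    S[iu] = rng.uniform(0.5, 2.0, size=len(iu[0]))
    S = S + S.T
    R = S * pi[None, :]
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(R, -R.sum(axis=1))
    total = -float(pi @ np.diag(R))
    return R / total, pi
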