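"""Shared fixtures.

The expensive sampling fixtures (neutral ensemble, selection chains,
million-sequence propensity sample) are session-scoped so that the
phenotype-distribution and propensity tests reuse one computation.
"""

import numpy as np
import pytest

import aggrevol as ag


@pytest.fixture(scope="session")
def matrix() -> ag.ContactMatrix:
    return ag.load_contact_matrix()


@pytest.fixture(scope="session")
def model() -> ag.MutationModel:
    return ag.MutationModel()


@pytest.fixture(scope="session")
def params_ref() -> ag.PhysicalParams:
    """Reference solution conditions: phi = 0.01 M, omega = 24."""
    return ag.PhysicalParams(phi=0.01)


@pytest.fixture(scope="session")
def neutral_ensemble(matrix, model, params_ref):
    """50 000 i.i.d. random sequences with canonical energies and phenotypes."""
    rng = np.random.default_rng(20240)
    fa, fb, e_aa, e_bb, e_ab = ag.random_surface_sample_arrays(
        50_000, model, matrix, rng, return_energies=True
    )
    n = e_aa.size
    p2_star = np.empty(n)
    p_fib = np.empty(n)
    for i in range(n):
        p = ag.phenotype(ag.InterfaceEnergies(e_aa[i], e_bb[i], e_ab[i]), params_ref)
        p2_star[i] = p.P2_star
        p_fib[i] = p.P_fib
    return dict(face_a=fa, face_b=fb, E_AA=e_aa, E_BB=e_bb, E_AB=e_ab,
                P2_star=p2_star, P_fib=p_fib)


@pytest.fixture(scope="session")
def selection_chains(matrix, model):
    """Full-length Metropolis chains (300 000 generations, 5 000 burn-in)
    under the three positive selection schemes at Ne*sigma = 25."""
    chains = {}
    for name, seed in (("dimer", 101), ("fibril", 102), ("oriented_fibril", 103)):
        scheme = ag.SelectionScheme(name, ne_sigma=25.0, phi_fitness=0.01)
        chains[name] = ag.run_mcmc(scheme, model, matrix, 300_000,
                                   burn_in=5000, seed=seed)
    return chains


@pytest.fixture(scope="session")
def neutral_propensities(matrix, model):
    """Propensity table over one million neutral sequences."""
    rng = np.random.default_rng(777)
    return ag.neutral_propensity_table(1_000_000, model, matrix, rng)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
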