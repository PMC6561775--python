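"""Metropolis sampling of surface sequences under selection.

Sequences evolve in the strong-selection weak-mutation regime: one
mutation segregates at a time, so the stationary frequency of sequence k
is its neutral mutational frequency reweighted by exp(2*Ne*s(k)).  The
sampler proposes a descendant by whole-sequence replication with
independent per-site mutation (site i is replaced by j != i with
probability u*pi_j) and accepts it with probability
min(1, exp(2*Ne*delta_s)); on rejection a second copy of the parent is
recorded, so simple means over the recorded chain estimate ensemble
averages.

Five fitness schemes are supported, each defining the selection
coefficient (in units of the selection-strength constant sigma) from the
aggregation phenotype at a fixed concentration:

  neutral          s = 0
  dimer            s = +P2*      (closed AA dimers favoured)
  anti_fibril      s = -P_fib
  fibril           s = +P_fib
  oriented_fibril  s = +P_ori

The user-facing strength is the compound product Ne*sigma; the factor 2
of the fixation-bias exponent is applied internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .aggregation import AggregationPhenotype, PhysicalParams, phenotype
from .contact_model import (
    ContactMatrix,
    InterfaceEnergies,
    ProteinSurfaces,
    SurfaceFace,
    SEQUENCE_LENGTH,
    protein_interface_energies,
)

__all__ = [
    "SCHEME_NAMES",
    "MutationModel",
    "SelectionScheme",
    "EvolutionChain",
    "ChainSummary",
    "mutate",
    "selection_coefficient",
    "acceptance_probability",
    "metropolis_step",
    "run_mcmc",
    "chain_summary",
]

SCHEME_NAMES = ("neutral", "dimer", "anti_fibril", "fibril", "oriented_fibril")


@dataclass(frozen=True)
class MutationModel:
    """Per-site mutation kernel r_ij = u * pi_j.

    u    overall rate constant; it sets proposal step size only and does
         not affect stationary frequencies.
    pi   stationary amino-acid frequencies of the mutation process
         (default uniform 0.05).
    """

    u: float = 0.05
    pi: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (20,) or (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must be 20 nonnegative frequencies summing to 1")
        if not 0.0 <= self.u <= 1.0:
            raise ValueError(f"u must be in [0, 1], got {self.u}")
        object.__setattr__(self, "pi", pi)


@dataclass(frozen=True)
class SelectionScheme:
    """One of the five fitness schemes.

    ne_sigma     compound selection strength Ne*sigma (>= 0).
    phi_fitness  concentration (mol/L) at which the phenotype enters
                 fitness.
    """

    name: str
    ne_sigma: float = 25.0
    phi_fitness: float = 0.01

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise ValueError(
                f"unknown scheme {self.name!r}; choose from {SCHEME_NAMES}"
            )
        if self.ne_sigma < 0:
            raise ValueError(f"ne_sigma must be >= 0, got {self.ne_sigma}")


def mutate(
    parent: ProteinSurfaces, model: MutationModel, rng: np.random.Generator
) -> ProteinSurfaces:
    """Replicate with mutation: each site is hit with probability u and
    redrawn from pi (a redraw may restore the parent residue, giving the
    required off-diagonal rate u*pi_j)."""
    seq = np.concatenate([parent.face_a.indices, parent.face_b.indices])
    hit = rng.random(SEQUENCE_LENGTH) < model.u
    n_hit = int(hit.sum())
    if n_hit:
        seq = seq.copy()
        seq[hit] = rng.choice(20, size=n_hit, p=model.pi).astype(seq.dtype)
    return ProteinSurfaces(SurfaceFace(seq[:16]), SurfaceFace(seq[16:]))


def selection_coefficient(
    phen: AggregationPhenotype, scheme: SelectionScheme
) -> float:
    """Selection coefficient in units of sigma."""
    if scheme.name == "neutral":
        return 0.0
    if scheme.name == "dimer":
        return phen.P2_star
    if scheme.name == "anti_fibril":
        return -phen.P_fib
    if scheme.name == "fibril":
        return phen.P_fib
    if scheme.name == "oriented_fibril":
        return phen.P_ori
    raise ValueError(f"unknown scheme {scheme.name!r}")  # pragma: no cover


def acceptance_probability(delta_s: float, ne_sigma: float) -> float:
    """min(1, exp(2 * Ne*sigma * delta_s)); delta_s in units of sigma."""
    if delta_s >= 0.0:
        return 1.0
    return math.exp(2.0 * ne_sigma * delta_s)


@dataclass
class _ChainState:
    protein: ProteinSurfaces
    energies: InterfaceEnergies
    phen: AggregationPhenotype
    s: float


def _evaluate(
    protein: ProteinSurfaces,
    scheme: SelectionScheme,
    matrix: ContactMatrix,
    params: PhysicalParams,
) -> _ChainState:
    energies, canonical = protein_interface_energies(protein, matrix)
    phen = phenotype(energies, params)
    return _ChainState(canonical, energies, phen, selection_coefficient(phen, scheme))


def metropolis_step(
    current: _ChainState,
    scheme: SelectionScheme,
    model: MutationModel,
    matrix: ContactMatrix,
    params: PhysicalParams,
    rng: np.random.Generator,
) -> tuple[_ChainState, bool]:
    """One proposal/acceptance step.

    Draw order is fixed for reproducibility: the 32 site-mutation draws
    come first, then (only when delta_s < 0) one acceptance draw.
    """
    proposal = mutate(current.protein, model, rng)
    candidate = _evaluate(proposal, scheme, matrix, params)
    log_alpha = 2.0 * scheme.ne_sigma * (candidate.s - current.s)
    # The acceptance draw is consumed only for strictly downhill moves,
    # so every scheme with ne_sigma = 0 replays the neutral chain exactly.
    if log_alpha >= 0.0 or rng.random() < math.exp(log_alpha):
        return candidate, True
    return current, False


@dataclass
class EvolutionChain:
    """Recorded Metropolis chain: one sample per proposal."""

    sequences: np.ndarray  # (generations, 32) uint8 residue indices
    energies: np.ndarray  # (generations, 3) columns E_AA, E_BB, E_AB
    phenotypes: np.ndarray  # (generations, 5) columns P1 P2 P2* P_fib P_ori
    accepted: np.ndarray  # (generations,) bool
    burn_in: int
    seed: int | None
    scheme: SelectionScheme
    phenotype_columns = ("P1", "P2", "P2_star", "P_fib", "P_ori")

    @property
    def generations(self) -> int:
        return len(self.accepted)

    def post_burn_in(self) -> "EvolutionChain":
        b = self.burn_in
        return EvolutionChain(
            self.sequences[b:], self.energies[b:], self.phenotypes[b:],
            self.accepted[b:], 0, self.seed, self.scheme,
        )


def run_mcmc(
    scheme: SelectionScheme,
    model: MutationModel,
    matrix: ContactMatrix,
    generations: int,
    burn_in: int = 5000,
    seed: int | np.random.Generator | None = None,
    omega: float = 24.0,
    initial: ProteinSurfaces | None = None,
    progress=None,
) -> EvolutionChain:
    """Run a full chain; every proposal contributes one recorded sample.

    The phenotype entering fitness (and recorded per sample) is evaluated
    at ``scheme.phi_fitness``.  A rejected proposal records a duplicate
    of the parent, which is required for unbiased chain means.
    """
    if not generations > burn_in >= 0:
        raise ValueError("need generations > burn_in >= 0")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    params = PhysicalParams(phi=scheme.phi_fitness, omega=omega)
    if initial is None:
        start = rng.integers(0, 20, size=SEQUENCE_LENGTH, dtype=np.uint8)
        initial = ProteinSurfaces(SurfaceFace(start[:16]), SurfaceFace(start[16:]))
    state = _evaluate(initial, scheme, matrix, params)

    sequences = np.empty((generations, SEQUENCE_LENGTH), dtype=np.uint8)
    energies = np.empty((generations, 3))
    phen = np.empty((generations, 5))
    accepted = np.empty(generations, dtype=bool)
    iterator = range(generations)
    if progress is not None:
        iterator = progress(iterator)
    for g in iterator:
        state, acc = metropolis_step(state, scheme, model, matrix, params, rng)
        sequences[g, :16] = state.protein.face_a.indices
        sequences[g, 16:] = state.protein.face_b.indices
        energies[g] = (state.energies.E_AA, state.energies.E_BB, state.energies.E_AB)
        p = state.phen
        phen[g] = (p.P1, p.P2, p.P2_star, p.P_fib, p.P_ori)
        accepted[g] = acc
    return EvolutionChain(
        sequences, energies, phen, accepted, burn_in,
        seed if isinstance(seed, int) else None, scheme,
    )


@dataclass(frozen=True)
class ChainSummary:
    """Post-burn-in chain means (rejection duplicates included)."""

    mean_P2_star: float
    mean_P_fib: float
    mean_P_ori: float
    mean_E_AA: float
    mean_E_BB: float
    mean_E_AB: float
    acceptance_rate: float
    n_samples: int


def chain_summary(chain: EvolutionChain) -> ChainSummary:
    post = chain.post_burn_in()
    if post.generations == 0:
        raise ValueError("no post-burn-in samples to summarise")
    e = post.energies.mean(axis=0)
    p = post.phenotypes.mean(axis=0)
    return ChainSummary(
        mean_P2_star=float(p[2]),
        mean_P_fib=float(p[3]),
        mean_P_ori=float(p[4]),
        mean_E_AA=float(e[0]),
        mean_E_BB=float(e[1]),
        mean_E_AB=float(e[2]),
        acceptance_rate=float(post.accepted.mean()),
        n_samples=post.generations,
    )
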