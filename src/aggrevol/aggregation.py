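"""Equilibrium statistics of linear aggregation.

Given the three interface energies (E_AA, E_BB, E_AB) of a protein and a
total subunit concentration phi, the equilibrium concentrations C_n of
linear chains of n subunits follow from a 2x2 transfer matrix over the
exposed-face state of a growing chain.  Every interface carries a
dimensionless statistical weight a_ij = exp(-beta*E_ij)/omega, where
omega is the number of orientational configurations a subunit can take
relative to its neighbour (24 for a cube on a cubic lattice).  Writing
y = c/c0 for the reduced free-monomer concentration, the chain spectrum
is

    C_n / c0 = y**n * (A_plus * lam_plus**(n-1) - A_minus * lam_minus**(n-1))

with lam_pm = a_AB +/- sqrt(a_AA * a_BB) the transfer-matrix eigenvalues
and A_pm the corresponding amplitudes (A_plus - A_minus = 1).  Mass
conservation phi = sum_n n*C_n closes the model and fixes c; from c all
phenotype probabilities follow in closed form:

  P1       fraction of subunits free in solution,
  P2       fraction in dimers of any kind,
  P2*      fraction in closed dimers bound through the strong AA face,
  P_fib    fraction in chains of three or more subunits,
  P_ori    fraction in oriented fibrils built from AB interfaces only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .contact_model import InterfaceEnergies

__all__ = [
    "PhysicalParams",
    "StatWeights",
    "AggregationPhenotype",
    "EXAMPLE_ENERGIES",
    "statistical_weight",
    "weights_from_energies",
    "transfer_eigenvalues",
    "amplitudes",
    "chain_concentration",
    "solve_monomer_concentration",
    "phenotype",
    "concentration_trajectory",
]

#: Interface-energy triples (E_AA, E_BB, E_AB) in kT for six exemplar
#: surface sequences spanning the phenotype range: a monomer (A), a
#: dimer-former (B), a strong dimer-former (C), a fibril former (D), a
#: strong fibril-former (E) and an oriented fibril-former (F).
EXAMPLE_ENERGIES: dict[str, InterfaceEnergies] = {
    "A": InterfaceEnergies(-2.68, -2.32, -2.80),
    "B": InterfaceEnergies(-12.06, -3.14, -5.25),
    "C": InterfaceEnergies(-15.82, -0.60, -2.80),
    "D": InterfaceEnergies(-9.08, -8.67, -5.68),
    "E": InterfaceEnergies(-12.28, -12.06, -12.01),
    "F": InterfaceEnergies(-4.53, -4.52, -8.18),
}

#: No physical 4x4 surface reaches energies anywhere near this; weights
#: below it would overflow double precision.
ENERGY_FLOOR_KT = -600.0


@dataclass(frozen=True)
class PhysicalParams:
    """Scalar physical parameters of the solution.

    phi    total subunit concentration, mol/L.
    omega  orientational-configuration count per interface (dimensionless).
    c0     reference concentration, mol/L.
    beta   inverse temperature in 1/kT; energies are supplied in kT so
           the Boltzmann exponent is dimensionless and beta defaults to 1.
    """

    phi: float
    omega: float = 24.0
    c0: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not self.phi > 0:
            raise ValueError(f"phi must be positive, got {self.phi}")
        if self.omega < 1:
            raise ValueError(f"omega must be >= 1, got {self.omega}")
        if not self.c0 > 0:
            raise ValueError(f"c0 must be positive, got {self.c0}")


@dataclass(frozen=True)
class StatWeights:
    """Dimensionless statistical weights of the three interface types."""

    a_AA: float
    a_BB: float
    a_AB: float

    @property
    def iso_geometric_mean(self) -> float:
        """sqrt(a_AA * a_BB), computed without overflowing the product."""
        return math.sqrt(self.a_AA) * math.sqrt(self.a_BB)


def statistical_weight(energy: float, params: PhysicalParams) -> float:
    """Boltzmann weight exp(-beta*E)/omega of a single interface."""
    if not math.isfinite(energy):
        raise ValueError(f"interface energy must be finite, got {energy}")
    if energy < ENERGY_FLOOR_KT:
        raise ValueError(
            f"interface energy {energy} kT is below the overflow floor "
            f"{ENERGY_FLOOR_KT} kT; no physical surface reaches this"
        )
    return math.exp(-params.beta * energy) / params.omega


def weights_from_energies(
    energies: InterfaceEnergies, params: PhysicalParams
) -> StatWeights:
    return StatWeights(
        a_AA=statistical_weight(energies.E_AA, params),
        a_BB=statistical_weight(energies.E_BB, params),
        a_AB=statistical_weight(energies.E_AB, params),
    )


def transfer_eigenvalues(a: StatWeights) -> tuple[float, float]:
    """Eigenvalues lam_pm = a_AB +/- sqrt(a_AA * a_BB) of the transfer matrix."""
    root = a.iso_geometric_mean
    return a.a_AB + root, a.a_AB - root


def amplitudes(a: StatWeights) -> tuple[float, float]:
    """Chain-spectrum amplitudes A_pm; A_plus - A_minus = 1 identically."""
    root = a.iso_geometric_mean
    a_plus = (a.a_AA + a.a_BB + 2.0 * root) / (4.0 * root)
    return a_plus, a_plus - 1.0


def chain_concentration(
    n: int, c: float, a: StatWeights, params: PhysicalParams
) -> float:
    """Equilibrium concentration C_n of chains of n subunits (mol/L)."""
    if n < 1:
        raise ValueError(f"chain length must be >= 1, got {n}")
    lam_p, lam_m = transfer_eigenvalues(a)
    a_p, a_m = amplitudes(a)
    y = c / params.c0
    return params.c0 * y**n * (a_p * lam_p ** (n - 1) - a_m * lam_m ** (n - 1))


def _mass_balance(y: float, a_p: float, a_m: float, lam_p: float, lam_m: float) -> float:
    """sum_n n*C_n / c0 as a function of y = c/c0 (monotone increasing)."""
    return a_p * y / (1.0 - lam_p * y) ** 2 - a_m * y / (1.0 - lam_m * y) ** 2


def solve_monomer_concentration(
    phi: float, a: StatWeights, params: PhysicalParams
) -> float:
    """Free monomer concentration c solving mass conservation.

    The right-hand side of the conservation law is a power series with
    nonnegative coefficients, hence strictly increasing in c on the
    physical interval 0 < c < min(phi, c0/lam_plus); the root is unique
    and is found by bracketed root-finding.
    """
    lam_p, lam_m = transfer_eigenvalues(a)
    a_p, a_m = amplitudes(a)
    target = phi / params.c0
    # At y = phi/c0 the balance already exceeds phi (the series is >= y),
    # so the target itself is a valid upper bracket unless the geometric
    # bound 1/lam_plus is tighter, where the balance diverges.
    if lam_p * target < 1.0:
        y_hi = target
    else:
        y_hi = (1.0 / lam_p) * (1.0 - 1e-13)

    def objective(y: float) -> float:
        return _mass_balance(y, a_p, a_m, lam_p, lam_m) - target

    y_lo = min(1e-300, y_hi * 1e-6)
    try:
        # xtol must not dominate at very dilute phi, where y is tiny and
        # the default absolute tolerance would leave O(xtol/phi) relative
        # error in the monomer fraction
        y = brentq(objective, y_lo, y_hi, rtol=8.9e-16, xtol=1e-300, maxiter=200)
    except ValueError as exc:  # pragma: no cover - guarded by monotonicity
        raise ArithmeticError(
            f"monomer bracketing failed for phi={phi}, weights={a}: {exc}"
        ) from exc
    return y * params.c0


@dataclass(frozen=True)
class AggregationPhenotype:
    """Equilibrium phenotype of one sequence at one concentration."""

    c: float
    P1: float
    P2: float
    P2_star: float
    P_fib: float
    P_ori: float
    #: P_n for n = 1..n_max (subunit-occupancy probabilities) plus the
    #: aggregate tail mass beyond n_max.
    P_n: np.ndarray = field(repr=False, default=None)
    tail: float = 0.0


def _oriented_fraction(c: float, phi: float, a_AB: float, c0: float) -> float:
    """Closed form of the oriented-fibril fraction.

    The concentration of subunits in oriented n-chains is
    n * c**n * a_AB**(n-1) / c0**(n-1) = n * c * x**(n-1) with
    x = c*a_AB/c0, so summing n >= 3:
    P_ori = (c/phi) * (1/(1-x)**2 - 1 - 2x).
    """
    x = c * a_AB / c0
    if x >= 1.0:  # pragma: no cover - excluded by lam_plus bound
        raise ArithmeticError(f"oriented-series ratio x={x} >= 1")
    return (c / phi) * (1.0 / (1.0 - x) ** 2 - 1.0 - 2.0 * x)


def phenotype(
    energies: InterfaceEnergies,
    params: PhysicalParams,
    n_max: int | None = None,
) -> AggregationPhenotype:
    """Full equilibrium phenotype from interface energies.

    P_fib is computed as the exact complement 1 - P1 - P2; the n-mer
    spectrum P_n is reported up to ``n_max`` (with explicit tail mass)
    when requested.
    """
    a = weights_from_energies(energies, params)
    phi, c0 = params.phi, params.c0
    c = solve_monomer_concentration(phi, a, params)
    y = c / c0
    p1 = c / phi
    c2 = 0.5 * y * y * (a.a_AA + 2.0 * a.a_AB + a.a_BB) * c0
    p2 = 2.0 * c2 / phi
    p_fib = 1.0 - p1 - p2
    p2_star = p2 * a.a_AA / (a.a_AA + a.a_BB + 2.0 * a.a_AB)
    p_ori = _oriented_fraction(c, phi, a.a_AB, c0)

    p_n = None
    tail = 0.0
    if n_max is not None:
        ns = np.arange(1, n_max + 1)
        lam_p, lam_m = transfer_eigenvalues(a)
        a_p, a_m = amplitudes(a)
        # group y with each eigenvalue: |y*lam| < 1 on the physical branch,
        # so the powers underflow harmlessly instead of lam**n overflowing
        with np.errstate(under="ignore"):
            c_n = c0 * y * (
                a_p * (y * lam_p) ** (ns - 1.0) - a_m * (y * lam_m) ** (ns - 1.0)
            )
        p_n = ns * c_n / phi
        tail = max(0.0, 1.0 - float(p_n.sum()))
    return AggregationPhenotype(
        c=c, P1=p1, P2=p2, P2_star=p2_star, P_fib=p_fib, P_ori=p_ori,
        P_n=p_n, tail=tail,
    )


def concentration_trajectory(
    energies: InterfaceEnergies,
    phi_grid,
    params: PhysicalParams | None = None,
    omega: float = 24.0,
) -> pd.DataFrame:
    """Phenotype table over a concentration grid (one row per phi)."""
    phi_grid = np.asarray(phi_grid, dtype=float)
    if phi_grid.size == 0 or (phi_grid <= 0).any():
        raise ValueError("phi grid must be non-empty and strictly positive")
    if (np.diff(phi_grid) < 0).any():
        raise ValueError("phi grid must be sorted ascending")
    base = params or PhysicalParams(phi=phi_grid[0], omega=omega)
    rows = []
    for phi in phi_grid:
        p = phenotype(energies, PhysicalParams(phi=phi, omega=base.omega,
                                               c0=base.c0, beta=base.beta))
        rows.append(
            dict(phi=phi, c=p.c, P1=p.P1, P2=p.P2, P2_star=p.P2_star,
                 P_fib=p.P_fib, P_ori=p.P_ori)
        )
    return pd.DataFrame(rows)
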