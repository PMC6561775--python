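# Methods

This note records the model definition, parameter defaults, and the
numerical and statistical choices made in `aggrevol`, in the package's
own terms.

## Contact potential

The packaged 20×20 potential (`src/aggrevol/data/bt_contact_matrix.tsv`)
is a knowledge-based residue-contact energy matrix in kT units,
referenced so that all threonine contacts are exactly zero. It is
symmetric, with grand mean −0.057 kT; a random 16-contact interface
therefore averages −0.912 kT. On load the matrix is validated for
shape, symmetry (to 1e-9) and, for the packaged file only, the grand
mean. Users may load alternative matrices from TSV with the same
alphabetical row/column order `ACDEFGHIKLMNPQRSTVWY`.

## Faces, rotations and canonical labelling

A 32-residue sequence maps to two 4×4 faces: residues 1–16 fill face A
row by row, residues 17–32 face B. Two faces can contact in four
rotational alignments; using 1-based (row, column) coordinates the
partner of position (r, c) on the other face is

| rotation | partner | fixed points |
|---|---|---|
| 0° | (5−r, c) | none |
| 90° | (c, r) | main diagonal (4) |
| 180° | (r, 5−c) | none |
| 270° | (5−c, 5−r) | anti-diagonal (4) |

Each map is an involution, so every pairing is counted consistently.
The interface energy is the minimum over the four rotations of the sum
of 16 contact energies. For an isologous (X–X) interface the 16 terms
pair up, which makes the variance of a random isologous interface
energy twice that of a heterologous one — a property the test suite
checks.

After computing `E_AA`, `E_BB`, `E_AB`, faces are relabelled if needed
so that `E_AA ≤ E_BB` (A is the stronger self-binding face). Ties keep
the original labels. `E_AB` is invariant under relabelling.

## Aggregation equilibrium

Statistical weights are `a_XY = exp(−β E_XY) / ω` with β = 1 (energies
already in kT), ω = 24 (the number of distinguishable orientations of a
cubic subunit) and reference concentration c₀ = 1 M. Energies below a
floor of −600 kT raise an error rather than overflow; physically
relevant interfaces are far above it.

Linear n-mer concentrations follow from the 2×2 transfer matrix
`T = [[a_AB, a_BB], [a_AA, a_AB]]` with eigenvalues
`λ± = a_AB ± sqrt(a_AA a_BB)` and amplitudes
`A± = (a_AA + a_BB ± 2 sqrt(a_AA a_BB)) / (4 sqrt(a_AA a_BB))`
(normalised so `A₊ − A₋ = 1`):

    C_n / c0 = y^n (A₊ λ₊^{n−1} − A₋ λ₋^{n−1}),  y = c / c0.

The free monomer concentration c solves the mass balance

    φ/c0 = A₊ y / (1 − λ₊ y)² − A₋ y / (1 − λ₋ y)².

This is solved with `scipy.optimize.brentq` at machine-precision
relative tolerance on the bracket (0, y_hi], where `y_hi = φ/c0` when
`λ₊ φ/c0 < 1` (the series converges at the trivial upper bound) and
`y_hi = (1/λ₊)(1 − 1e−13)` otherwise (just inside the geometric-series
radius). The objective is monotone on the bracket, so the root is
unique.

Reported phenotypes: `P1 = c/φ`, `P2 = 2 C₂/φ`,
`P_fib = 1 − P1 − P2`, the closed-dimer fraction
`P2* = P2 · a_AA / (a_AA + a_BB + 2 a_AB)` (the A–A-bound share of
dimers), and the oriented-fibril fraction. Chains built exclusively
from A–B junctions have `C_n^ori = c x^{n−1}` with `x = c a_AB / c0`,
giving the closed form

    P_ori = (c/φ) · (1/(1 − x)² − 1 − 2x).

All closed forms are verified in the tests against explicit
matrix-power and truncated-series oracles (to 1e-9), and
`P1 + P2 + P_fib = 1` is asserted to 1e-9 across random parameter
draws.

## Evolutionary sampler

Evolution is modelled in the origin–fixation (strong-selection /
weak-mutation) regime: the population is monomorphic and each
generation proposes mutations to the current sequence. The mutation
kernel draws, per site, a replacement from the background distribution
π (uniform by default) with probability u = 0.05; because a draw can
return the same residue, the realised per-site substitution rate is
u(1 − 1/20) = 0.0475.

A proposal with phenotype change Δs (s measured in units of the
selection intensity σ) is accepted with the Metropolis-form fixation
probability `min(1, exp(2 Ne σ Δs))`. Defaults: `Ne·σ = 25`, fitness
evaluated at φ = 0.01 M, ω = 24. Selection schemes: `neutral` (s = 0),
`dimer` (s = P2*), `fibril` (s = P_fib), `anti_fibril` (s = −P_fib),
`oriented_fibril` (s = P_ori). Rejected proposals record the parent
again, so chain averages are over the stationary distribution. The
uniform random acceptance draw is consumed only when the move is
strictly downhill, so a scheme with `Ne·σ = 0` replays the neutral
chain for the same seed exactly.

Default runs use 300,000 generations after a 5,000-generation burn-in —
long enough that the propensity tables and their correlations are well
converged (chain means converge much earlier, by ~50,000 generations).
Each 300,000-generation chain takes under a minute on one CPU.

## Propensities and correlations

For a sequence sample (an explicit array pair, an iterable of proteins,
or a post-burn-in MCMC chain), per-amino-acid face frequencies are
pooled over all positions after canonical relabelling and divided by π
to give propensities `p_A(i)`, `p_B(i)` (so Σᵢ πᵢ p_X(i) = 1 exactly).
Scores: `S_int(i) = ln(p_A(i)/p_B(i))` contrasts the binding face with
the passive face within one ensemble; `S_iso(i) = ln(p_A^dimer(i) /
p_A^oriented(i))` contrasts isologous against heterologous binding
faces across two ensembles. A zero count raises an error asking for a
larger sample rather than returning ±inf.

Contact-matrix predictors are `B_self(i) = B(i,i)`, `B_ave(i)` = row
mean, and `ΔB = B_ave − B_self`. Correlations use Pearson's r with the
two-sided t-test p-value (`scipy.stats.pearsonr`); zero-variance input
is rejected. External hydrophobicity/stickiness scales can be supplied
by the user as 20-value mappings or tables; none are bundled.

Neutral propensity tables default to 10⁶ i.i.d. sequences (about 6 s),
generated in chunks of 10⁵ with vectorised energy evaluation; the
`S_int`–`B_ave` correlation is stable to <0.02 between 10⁵ and 10⁶
samples.

## Reproducibility and I/O

All stochastic routines take an explicit `numpy` `Generator` or integer
seed. `scripts/acceptance.py` derives independent child streams from a
single `--seed` via `SeedSequence`. Tabular output is plain TSV (or
JSON / gzipped TSV) with a one-line header comment carrying the package
version and a 12-hex-digit hash of the run configuration, plus an
optional sidecar `.config` file; floats are written with 12 significant
digits, which round-trips to ~5e-12 relative precision.

## What the generators emulate — and what they do not

- The model is an equilibrium theory of *linear* aggregates of rigid
  cubic subunits with two binding faces. No nucleation kinetics, no
  branched or closed (ring) assemblies, no conformational change, and
  no explicit structure beyond the 4×4 contact map.
- Evolution is monomorphic origin–fixation dynamics: no polymorphism,
  recombination, or epistasis beyond what the phenotype map induces.
- The fitness-defining concentration (0.01 M) is deliberately high to
  place random sequences near the aggregation boundary; results at
  other φ can be explored via `PhysicalParams` or the `trajectory`
  command.
- Amino-acid background frequencies default to uniform; composition
  effects of realistic proteomes are not modelled.
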