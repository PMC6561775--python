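# aggrevol

Equilibrium self-assembly of model proteins coupled to an evolutionary
Metropolis sampler: why proteins that evolve to form symmetric dimers
rarely turn into runaway fibrils, and which amino acids make the
difference.

## The scientific problem

Many proteins function as symmetric homodimers, yet the same sticky
surfaces that hold a dimer together could in principle keep recruiting
monomers and grow an unbounded linear aggregate — a fibril. This
package implements a minimal statistical-mechanics model of that
trade-off and couples it to a population-genetics sampler, so one can
ask: what do sequences look like after long evolution under selection
for dimers, for fibrils, or for *oriented* (head-to-tail) fibrils, and
how do the resulting amino-acid preferences relate to the underlying
contact potential?

## The model

**Protein.** A protein is a 32-residue sequence split into two 4×4
square faces, A and B (the first 16 residues form face A). Two faces
bind in one of four rotational alignments; the interface energy is the
sum of 16 residue–residue contact energies, and each face pair adopts
its minimum-energy rotation:

    E_XY = min over 4 rotations of sum_{k=1..16} B(x_k, y_partner(k))

The contact energies `B(i,j)` come from a packaged 20×20
knowledge-based potential (in kT units, threonine-referenced; grand
mean exactly −0.057 kT). Faces are relabelled so that the stronger
self-interaction is always called A (`E_AA ≤ E_BB`).

**Aggregation equilibrium.** Monomers assemble into linear chains in
which each junction is an A–A, B–B or A–B interface. With statistical
weights `a_XY = exp(−E_XY)/ω` (orientational entropy penalty ω = 24,
reference concentration c₀ = 1 M), the concentration of n-mers follows
from a 2×2 transfer matrix with eigenvalues

    λ± = a_AB ± sqrt(a_AA · a_BB)

    C_n / c0 = y^n (A₊ λ₊^{n−1} − A₋ λ₋^{n−1}),   y = c / c0

where c is the free monomer concentration, fixed by mass balance at
total concentration φ:

    φ/c0 = A₊ y / (1 − λ₊ y)² − A₋ y / (1 − λ₋ y)²

From the solution the package reports the monomer fraction `P1`, dimer
fraction `P2`, *closed* dimer fraction `P2*` (dimers bound through the
strong A–A interface), fibril fraction `P_fib = 1 − P1 − P2`, and the
oriented-fibril fraction `P_ori` (chains using only A–B junctions, in
closed form).

**Evolution.** Sequences evolve by origin–fixation (strong-selection /
weak-mutation) Metropolis dynamics: one proposed substitution per
generation (per-site rate u = 0.05 toward a uniform background π),
accepted with probability `min(1, exp(2·Ne·σ·Δs))` where s is the
selected phenotype in units of σ — `P2*` (dimer scheme), `P_fib`
(fibril), `−P_fib` (anti-fibril), `P_ori` (oriented fibril) — at a
fitness-defining concentration φ = 0.01 M and `Ne·σ = 25`. Rejected
proposals leave the parent in the sample, as in the stationary
distribution.

**Propensities.** From any sequence sample the package computes
per-amino-acid face propensities `p_A(i)`, `p_B(i)` relative to π, the
interface score `S_int = ln(p_A/p_B)`, the isologous-vs-heterologous
score `S_iso = ln(p_A^dimer / p_A^oriented)`, and their Pearson
correlations with contact-matrix predictors (`B_self`, row-mean `B_ave`
and `ΔB = B_ave − B_self`) or with user-supplied external scales.

## Worked example

```python
import aggrevol as ag

matrix = ag.load_contact_matrix()

# a sequence with a hydrophobic A face and a polar/charged B face
seq = "CLVFMICFWVLIAMVFDKEDRKGQENSHTPRY"
protein = ag.ProteinSurfaces.from_sequence(seq)
energies, _ = ag.protein_interface_energies(protein, matrix)
print(energies)
# InterfaceEnergies(E_AA=-11.46, E_BB=-2.54, E_AB=1.71)

p = ag.phenotype(energies, ag.PhysicalParams(phi=0.01))
print(f"P1={p.P1:.4f} P2*={p.P2_star:.4f} P_fib={p.P_fib:.4f}")
# P1=0.1462 P2*=0.8442 P_fib=0.0096
```

The strong, self-complementary A face drives nearly all material into
closed A–A dimers; because the B face is inert, chains cannot extend
and the fibril fraction stays below 1%. Compare a *fibril former* whose
two faces are both sticky, entered by its interface energies directly:

```python
p = ag.phenotype(ag.InterfaceEnergies(-9.08, -8.67, -5.68),
                 ag.PhysicalParams(phi=0.01))
print(f"P_fib={p.P_fib:.4f}")   # P_fib=0.6031
```

The same computation is available from the command line, with a
provenance header and a sidecar config file:

```console
$ aggrevol phenotype --phi 0.01 --eaa -9.08 --ebb -8.67 --eab -5.68 --out phen.tsv
INFO wrote phen.tsv
$ cat phen.tsv
# aggrevol 0.1.0 config=78dd0ae23b17
id      phi     c       P1      P2      P2_star P_fib   P_ori
input   0.01    0.0018359593621 0.18359593621   0.213331252414  0.12328458631   0.603072811376  0.000285116625228
```

Other subcommands: `aggrevol energy` (interface energies for FASTA
sequences), `aggrevol trajectory` (phenotype vs. total concentration),
`aggrevol evolve` (Metropolis chains), `aggrevol propensity`
(amino-acid propensity tables, scores and correlations) and
`aggrevol fixtures` (small test inputs).

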