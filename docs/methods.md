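# Methods

This note records the scientific content of `amideshift`: the models it
implements, the parameter choices that matter, what the synthetic fixtures
do and do not emulate, and the numerical conventions.

## Additive shift model

The predicted quantity is the backbone amide proton chemical shift,
DSS-referenced, decomposed as

δ(H^N) = δ_BB(φ,ψ) + δ_1°HB + δ_2°HB + δ_3° + δ_RC.

The decomposition is exactly additive by construction; `TermBreakdown.total`
is the literal sum of the five fields, and the test suite asserts this to
1e−12 on every fixture. The additivity is a modeling *assumption* about the
underlying electronic structure, not a theorem — cooperative hydrogen-bond
effects beyond the tabulated tertiary increments are ignored.

### Backbone term

A truncated 2-D trigonometric series in (φ, ψ) evaluated from
`data/backbone_series.txt` (basis codes `cc/cs/sc/ss` for the four
cosine/sine products), followed by the affine scaling `a·x + b`
(default (1, 0), configurable). The scaling exists because surfaces of this
kind are derived at a particular level of quantum-chemical theory and basis
set and need re-anchoring against any new reference data. The shipped
coefficients are this package's own parameterization: a ~5.2 ppm baseline
with harmonics of a few tenths of a ppm, chosen to reproduce the magnitude
of backbone-conformational shift dispersion seen in amide protons. They are
*not* fitted to quantum-chemical calculations, and users with access to a
published (φ,ψ) hypersurface should drop its coefficients into the same
file format.

### Primary hydrogen-bond term

Acceptors are classified as backbone amide, side-chain amide, carboxylate
(ASP/GLU/OXT), or alcohol (SER/THR/TYR). Amide acceptors use the closed
form `A·exp(−b·r_HO)·cos²θ₂` with A = 52 ppm, b = 1.5 Å⁻¹
(`data/hbond_primary_amide.txt`): ~2.5 ppm at a typical 1.9 Å / 155°
amide–amide geometry, with the steep exponential distance dependence that
makes H^N shifts useful for refinement (≈ −3.7 ppm/Å there). Carboxylate
and alcohol acceptors interpolate bilinearly on (r_HO, θ₂) grids
(`data/surface_*.txt`, 1.5–3.0 Å × 90–180°); out-of-range geometries clamp
to the boundary with a logged warning rather than extrapolate.
Interpolation reproduces grid nodes exactly, and values between nodes are
bounded by the surrounding node extrema.

A proton with no acceptor inside the detection gate receives the constant
**2.07 ppm**, the value for an energy-minimized water/N-methylacetamide
geometry. It is treated as a constant — solvent-exposure fluctuations in
an ensemble are not modeled.

### Secondary and tertiary terms

The secondary term applies when the carbonyl oxygen of the proton's own
amide group (the C=O of residue i−1) accepts a bond; it reuses the
exponential machinery with its own amplitude (9 ppm, ~0.4 ppm at typical
geometry). The tertiary term is a table of constant increments
(`data/tertiary_increments.txt`): +0.25 ppm when the primary acceptor's
amide group itself donates a bond, +0.10 ppm when the donor bonding to the
own-carbonyl is itself chained. These discrete increments are a coarse
stand-in for network polarization; their discontinuity is a known
limitation (a bond flickering across the gate moves the prediction by the
full increment).

### Ring current

Point-dipole approximation, δ_RC = Σ i·B·(1 − 3cos²θ)/r³ with
B = 30.42 ppm·Å³, r the vector from ring center to proton and θ its angle
to the ring normal (SVD plane fit of the ring heavy atoms). Intensities
per ring kind (PHE6 1.00, TYR6 0.81, TRP5 0.90, TRP6 1.04, HIS5 0.53) live
in `data/ring_current.txt`. Protons on the ring axis are shielded
(negative contribution), equatorial protons deshielded, zero at the magic
angle; the point-dipole form is inaccurate closer than ~3 Å from a ring
center and takes no account of ring protonation states.

## Hydrogen-bond detection

For every backbone amide proton (prolines and chain N-termini excluded),
candidate acceptors are all classified oxygens except the carbonyl oxygens
of the donor's own peptide plane (residues i−1 and i). The gate is
r_HO ≤ 2.5 Å and N–H···O ≥ 120°; both are configurable
(`hydrogen_bond_gate` in the YAML). Among gated candidates the smallest
r_HO wins, ties broken by the larger N–H···O angle — bifurcated bonds are
therefore represented by their dominant branch only. The dihedral ρ
(H···O=C–X) uses X = CA of the acceptor residue. Structures must carry
explicit amide hydrogens (N–H within 0.8–1.2 Å); no protonation is
performed, and a structure failing this check is rejected with an error
naming the first offending residue.

## Couplings and RDCs

h3J(NC') uses `J = A·exp(−b·r_HO)·cos²θ₁·cos²θ₂` with A = −360 Hz,
b = 3.2 Å⁻¹ (`data/jcoupling.txt`; the Barfield-style distance decay with
symmetric angular factors in the N–H···O and H···O=C angles). This gives
≈ −0.3 to −0.9 Hz for intact amide–amide bonds and < 0.01 Hz beyond 6 Å,
and is defined only for amide–amide bonds. Ensemble statistics use the
per-bond mean over conformers, the population SD about that mean, and the
RMSD of means against experiment; a bond broken in some conformers
contributes 0 Hz there.

RDCs are backbone N–H only: D_i = u_i^T S u_i with the five independent
Saupe components fitted by SVD least squares (rank checked; collinear N–H
sets are rejected with a message naming the deficiency). The Hz scale of
the dipolar constant is absorbed into S. In ensemble mode the design rows
are averaged over conformers so one tensor fits all structures
simultaneously. The Q-factor uses the plain Σ D_exp² denominator (ratio to
experiment), not the Da-scaled variant.

## Bayesian refinement

The posterior is p(X|D) ∝ exp(−E(X)/k_B T) · Π_i N(Δδ_i | 0, σ_i²) with
T = 300 K by default and k_B in kcal/(mol·K). σ_i is assigned from the
proton's primary-bond class: 0.3 / 0.5 / 0.8 / 1.2 ppm for backbone amide /
side-chain amide / alcohol-or-carboxylate / solvent-exposed-or-other —
reflecting that the solvent-exposure model is much cruder than the
amide–amide surface. The formulation assumes the prior is also an adequate
prior for the shift deviations; no additional correction term is modeled.

Sampling is Metropolis–Hastings with symmetric Gaussian single-torsion
moves: 25 % backbone (φ/ψ, default σ 2°) and 75 % side-chain (χ1, default
σ 10°), falling back to backbone when no side-chain torsion exists.
Rotating a torsion moves all downstream atoms of the chain rigidly
(single-chain refinement only). Rejected moves restore the previous state
object bit-exactly, and a fixed seed reproduces the full trace. Conformers
are saved every 10,000 steps by default.

### Prior energy

The molecular-mechanics prior is a contract, not a commitment: any
callable `Structure -> kcal/mol` plugs in. The shipped `DefaultEnergy` is
a deliberately coarse desk-scale regularizer with three pieces:

- soft-sphere sterics, 10·(2.4 − d)² kcal/mol for heavy-atom pairs ≥ 2
  residues apart closer than 2.4 Å (N/O pairs exempt so hydrogen bonds may
  approach);
- a flat-bottomed hydrogen-bond well: −3 kcal/mol for any detected bond
  with r_HO in 1.75–2.35 Å, Gaussian shoulders (width 0.15 Å) outside.
  The flat bottom is deliberate — the prior should reward an intact bond
  but must not impose its own preferred bond *length*, which would bias
  exactly the geometry the likelihood is supposed to determine;
- a harmonic restraint on every backbone torsion to the starting
  structure, k = 0.15 kcal/(mol·deg²) (≈ 2° SD per torsion at 300 K),
  standing in for the conformational basin a real force field defines
  around a refinement start. Without a restraint of roughly this
  stiffness the posterior has soft directions in which backbone-term
  changes compensate hydrogen-bond-term changes, and bond lengths become
  unidentifiable from shifts alone.

## Synthetic fixtures

`fixtures` builds every test input programmatically: poly-alanine peptides
with ideal bond lengths/angles at exact requested (φ, ψ) (NeRF chain
construction), optional F/Y/W/H/S/D/N residues from planar ring and
side-chain templates, two-dipeptide dimers posed at exact (r_HO, θ₂, θ₁)
nodes emulating formamide/N-methylacetamide scans, and forward-model shift
/ coupling / RDC tables with Gaussian noise and stored ground truth. All
fixtures are byte-identical for fixed parameters and seed.

What they do not emulate: real side-chain rotamer distributions, solvent,
crystal contacts, protonation heterogeneity, or the correlated structural
noise of experimental ensembles. Tests passing on these fixtures validate
the geometry, the term evaluation, the estimators and the sampler — they
do not certify prediction accuracy on real proteins, which depends on
coefficient sets this package ships only as replaceable defaults.

## Problem sizes and numerical choices

The validation suite runs at deliberately small scale: 3–12-residue
peptides, 25,000–60,000 MC steps, 50-conformer ensembles. The shift-driven
recovery check uses an 8-residue helix, noiseless synthetic shifts, a
uniform 0.05 ppm likelihood σ, and a start perturbed by 2° SD per backbone
torsion; it requires ensemble-mean H···O lengths within 0.05 Å of the
generating conformer. Dihedrals follow the IUPAC sign convention in
(−180°, 180°]; collinear atom quadruples raise rather than return a
default. Ring normals are sign-normalized (first nonzero component
positive) so atom-order flips cannot change downstream cos² values.
Altloc handling keeps blank or 'A' records; occupancy is ignored.
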