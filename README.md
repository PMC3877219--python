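# amideshift

Backbone amide proton (H^N) chemical shifts are among the most sensitive
NMR probes of the amide–amide hydrogen-bond network that holds protein
secondary structure together: the shift perturbation grows exponentially
as the H···O distance shortens. `amideshift` is a toolkit for structural
biologists and NMR spectroscopists that

- predicts H^N chemical shifts from a protein structure with explicit
  hydrogens, as a sum of physically interpretable additive terms,
- back-calculates trans-hydrogen-bond scalar couplings h3J(NC') and N–H
  residual dipolar couplings (RDCs) with SVD alignment-tensor fitting and
  Q-factors, and
- refines structures against experimental shift tables by Markov chain
  Monte Carlo sampling from a Bayesian posterior.

## The model

For each backbone amide proton the shift (ppm, DSS-referenced) is

```
δ(H^N) = δ_BB(φ, ψ) + δ_1°HB + δ_2°HB + δ_3° + δ_RC
```

* `δ_BB` — a truncated 2-D trigonometric series in the backbone torsions
  (φ, ψ), with an affine scaling `a·x + b` exposed in the configuration.
* `δ_1°HB` — the primary hydrogen bond donated by the proton itself.
  Amide acceptors use a closed-form exponential surface
  `A·exp(−b·r_HO)·cos²θ₂` (θ₂ = H···O=C angle); carboxylate and alcohol
  acceptors interpolate bilinear lookup tables; a proton with no acceptor
  inside the detection gate gets the water-model constant **2.07 ppm**.
* `δ_2°HB` — a smaller perturbation when the carbonyl oxygen of the
  proton's own amide group accepts a hydrogen bond.
* `δ_3°` — small tabulated increments for polarization when a bonding
  partner is itself hydrogen bonded.
* `δ_RC` — the point-dipole ring-current term
  `i·B·(1 − 3cos²θ)/r³` with `B = 30.42 ppm·Å³` and per-ring-kind
  intensities `i` (PHE/TYR six-rings, TRP five- and six-rings, HIS).

Couplings follow the Barfield-style closed form
`J = A·exp(−3.2 r_HO)·cos²θ₁·cos²θ₂` (Hz); the Q-factor is
`sqrt(Σ(D_calc − D_exp)² / Σ D_exp²)`.

Refinement samples the posterior
`p(X | D) ∝ exp(−E(X)/kT) · Π_i N(Δδ_i | 0, σ_i²)` at 300 K with
Metropolis–Hastings over torsion moves. The likelihood width σ_i depends
on the primary-bond class of each proton: 0.3 ppm (backbone amide),
0.5 ppm (side-chain amide), 0.8 ppm (alcohol/carboxylate), 1.2 ppm
(solvent-exposed/other). The prior energy is pluggable (any callable
`Structure -> kcal/mol`); the shipped default combines soft-sphere
sterics, a flat-bottomed hydrogen-bond well and a harmonic torsion
restraint to the starting structure.

All numerical coefficients live in plain-text data files under
`src/amideshift/data/` so the algorithms can be exercised against any
parameterization; see `docs/methods.md` for their provenance and the
model's assumptions and limitations.

## Worked example

Generate an ideal 12-residue α-helix, predict its shifts, and score the
prediction against a shift table:

```bash
$ amideshift fixtures make --kind helix --n 12 --out helix.pdb
$ amideshift predict --pdb helix.pdb --out shifts.csv
wrote 10 predictions (1 conformer(s)) to shifts.csv
```

`shifts.csv` holds one row per eligible amide proton (prolines and the
chain termini carry no prediction) with the full term breakdown:

```
chain,res_index,res_name,total_ppm,backbone,primary_hb,secondary_hb,tertiary,ring_current,acceptor_class
A,2,ALA,7.5557,5.0711,2.07,0.3146,0.1,0.0,NONE
A,3,ALA,7.5550,5.0709,2.07,0.3142,0.1,0.0,NONE
```

Residue 2 sits before the first i→i−4 helical bond, so its primary term
is the solvent-exposed constant 2.07 ppm; interior residues bond to the
carbonyl four residues back and pick up the exponential amide–amide
surface instead. Scoring against a table (`amideshift score --pred
shifts.csv --exp exp.csv`) prints the RMSD, Pearson r and a per-class
RMSD breakdown.

The same structure's couplings and RDC agreement:

```
$ amideshift couplings --pdb helix.pdb
 donor_res  acceptor_res   mean_hz  sd_hz
         5             1 -0.321935    0.0
         6             2 -0.320761    0.0
...
$ amideshift qfactor --pdb helix.pdb --rdc rdc.csv
Q-factor: 0.0014
```

(h3J values near −0.3 Hz for a 2.1 Å helical bond; the Q-factor here is
nonzero only through PDB coordinate rounding, since the example RDCs were
synthesized from the same helix.)

Refinement from Python, statsmodels-style:

```python
from amideshift import RefinementModel, ShiftTable, parse_structure

start = parse_structure("start.pdb")
shifts = ShiftTable.from_csv("exp_shifts.csv")
results = RefinementModel(start, shifts).fit(n_steps=100_000, seed=1)
print(results.summary())
results.to_pdb("ensemble.pdb")
```

`results` carries the saved conformer ensemble, a step-by-step trace
(energy, log-posterior, shift RMSD, acceptance rate), per-bond ensemble
hydrogen-bond statistics (`results.hbond_length_means()`), and ensemble
shift averages.

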