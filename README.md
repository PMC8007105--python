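# coevomc

Coevolutionary contact potentials embedded in a coarse-grained Monte Carlo
model of protein monomers and dimers — built for studying sequence-dependent
dimerization (the motivating system is the extracellular domains of classical
cadherins, whose adhesive specificity is set by weak, structurally
heterogeneous trans interactions).

The package takes a protein-family alignment and turns it into a simulatable
energy model, with no knowledge of the native structure:

1. **Alignment processing** — read a Stockholm/FASTA family alignment,
   project it onto the sequence of a reference structure (dropping columns
   where the reference has gaps), and discard sequences more than 90%
   identical to a kept one.
2. **Coupling inference** — fit a Potts model (fields `h_I(σ)`, couplings
   `J_IK(σ,τ)`, q = 21 states including the gap) by maximizing the
   pseudolikelihood under an informative l2 regularizer centered on a
   knowledge-based statistical potential `ε(σ,τ) = −log f(σ,τ)` built from
   side-chain contact frequencies:

   ```
   L(h, J) = −log PL(h, J | MSA)
             + α Σ_{I<K,σ,τ} (J_IK(σ,τ) − ε(σ,τ))²  + λ_h Σ h²
   ```

   Centering the penalty on ε injects prior contact knowledge where the
   alignment statistics are thin and removes the gauge degeneracy, so the
   optimum is unique. The tensor is then projected onto the sequence(s) of
   interest, `J_ij = J_ij(σ_i, σ_j)`, and normalized so that the RMS of
   off-diagonal elements is 1.
3. **Coarse-grained model** — each residue is four beads (N, CA, C, and one
   side-chain bead at the side chain's center of mass); bond lengths and
   angles are fixed at construction, so the degrees of freedom are the
   backbone dihedrals and rigid-body placements. The energy is

   ```
   E = Σ hard-core (J_HC → ∞ below R_HC = 2 Å)
     + ε₀ Σ J_ij θ(R − r_ij)                (side-chain contacts, R = 8.5 Å)
     − ε_dih Σ_i [ w_i^α e^(−Δ_α²/2σ_α²) + w_i^β e^(−Δ_β²/2σ_β²) ]
   ```

   with ε₀ = −1 (positive couplings attract), ε_dih = 90, α/β dihedral
   centers (−63°, −44°)/(−105°, −140°), σ_α = 30°, σ_β = 40°, and optional
   infinite square wells on CA–CA pairs (e.g. calcium-rigidified contacts).
4. **Sampling** — Metropolis MC with single/multiple dihedral flips, pivots
   and rigid rototranslations (all geometry-exact); low-temperature
   annealing (T = 10⁻³) to remove steric clashes; parallel tempering with
   adjacent-replica exchanges every 1000 steps; umbrella production runs
   with the inter-chain (trans) energy rescaled by k < 1.
5. **Observables** — umbrella reweighting `w(r) ∝ exp(−β(1−k)E_trans(r))`;
   bound fraction f_B (any attractive inter-chain side-chain contact);
   dissociation constant of two molecules in a box of volume V,

   ```
   k_D = 2 (1 − f)² / (f · N_A · V)
   ```

   plus contact-probability maps, RMSD, per-residue fluctuations, specific
   heat, conformational clustering and pair distance distributions.

## Worked example

`examples/01_infer_couplings.py` samples a 3000-sequence alignment from a
Potts model with five planted couplings and re-infers them:

```
alignment: 3000 sequences x 6 positions
pair couplings ranked by ||J_IK||_F (top 7):
  (0,2) 2.766 *
  (2,5) 2.710 *
  (0,3) 2.646 *
  (1,4) 2.639 *
  (3,4) 2.632 *
  (1,3) 0.439
  (0,5) 0.437
```

The five starred (planted) pairs rank first with a ~6× score margin — the
inference recovers the interaction structure from sequences alone.
`examples/03_dimer_dissociation.py` runs a toy dimer and converts its bound
fraction into a dissociation constant; it also prints the closed-form
reference point

```
k_D = 166 uM in 3.2e4 nm^3 -> f_B = 0.303 (printed value: 0.3)
```

i.e. in a two-molecule box of 3.2×10⁴ nm³ (≈100 μM nominal concentration),
a dissociation constant of 166 μM corresponds to the chains being bound 30%
of the time. `examples/02_sample_monomer.py` and
`examples/04_umbrella_reweighting.py` demonstrate dihedral-bias folding and
umbrella-sampling recovery of f_B.

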