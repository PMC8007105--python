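# Methods

## The model

A protein chain is reduced to four beads per residue: the backbone N, CA
and C atoms plus one side-chain bead (SC) at the mass-weighted centroid of
the side chain's heavy atoms (glycine: SC coincides with CA; this keeps the
bead count uniform and makes the glycine SC inert in practice, since
same-residue pairs are excluded from every interaction). Bond lengths and
bond angles — N–CA, CA–C, CA–SC, peptide C–N, and every backbone-vertex
angle including the two SC attachment angles — are recorded at construction
and held fixed: conformational freedom lives entirely in the backbone φ/ψ
torsions and rigid-body placement. The peptide ω torsion is likewise
frozen at its construction value because no move rotates about the C–N
bond. All coordinates are in Å; box sizes and volumes are quoted in nm/nm³
because the dissociation-constant relation uses V in nm³.

The configurational energy has four terms:

* **Hard core.** Any bead pair closer than R_HC = 2 Å is forbidden
  (infinite energy), excluding pairs within one residue and the bonded
  C(i)–N(i+1) pair, whose distances are fixed by construction. The box has
  hard walls (cubic or spherical, both implemented; the box volume is what
  matters thermodynamically).
* **Contacts.** Side-chain pairs within R = 8.5 Å contribute ε₀·J_ij with
  ε₀ = −1, where J is the coupling matrix projected from the family model
  (cis within a chain, requiring sequence separation |i−j| ≥ 3; trans
  between chains, no separation filter). The contact function is a sharp
  step, inclusive at r = R. Sign convention: positive projected couplings
  are attractive (negative energy), and a contact is called attractive iff
  its contribution is negative — the dimer definition below relies on this.
* **Dihedral bias.** Each defined φ and ψ contributes a negative
  propensity-weighted pair of Gaussian wells,
  −ε_dih·[w^α·exp(−Δ_α²/2σ_α²) + w^β·exp(−Δ_β²/2σ_β²)], with α centers
  (−63°, −44°), β centers (−105°, −140°), σ_α = 30°, σ_β = 40°, and angular
  differences wrapped to (−180°, 180°]. Per-residue propensities w^α, w^β
  come from a 3-column text table (e.g. exported from a secondary-structure
  predictor); defaults are zero.
* **Restraints.** Optional infinite square wells on CA–CA distances (used
  to mimic the rigidifying calcium sites between cadherin EC domains).
  Well bounds default to the built structure's native distance ± 1 Å when
  constructed from a reference, and are fully configurable.

Defaults ε₀ = −1, ε_dih = 90, α = 10⁻⁵ (coupling regularizer) are the
model's standard operating point; all are exposed in `EnergyParams` /
`fit_plm` for parameter scans.

## Coupling inference

The family model is a q = 21-state Potts model (20 residues + gap; the gap
is retained as an ordinary state rather than marginalized). It is fit by
minimizing the negative log-pseudolikelihood — the sum over sequences and
sites of −log P(σ_I | σ_{−I}) — plus two penalties: an l2 term on the
fields (λ_h = 0.01, conventional and weakly informative, since no value is
standard for this setting) and the informative coupling penalty
α·Σ_{I<K,σ,τ}(J_IK(σ,τ) − ε(σ,τ))², centered on the statistical potential
rather than on zero. The center is extended to the gap state by 0 (no
structural statistics exist for gaps). Because the penalty is strictly
convex in J and anchored at a fixed point, the optimum is unique: the fit
is gauge-stable, verified by refitting from random initializations.

All parameters (fields plus the L(L−1)/2 free symmetric coupling blocks)
are optimized jointly with L-BFGS using the exact analytic gradient
(validated against central finite differences to <10⁻⁵ relative error).
A joint symmetric fit was chosen over the common asymmetric-then-average
device: at these problem sizes it is equally cheap, and it makes the
uniqueness argument exact rather than approximate.

The statistical potential is ε(σ,τ) = −log f(σ,τ) with f the
pseudocount-regularized (+1) relative frequency of side-chain contacts
(SC–SC pairs within 8.5 Å, |i−j| ≥ 3 within a chain) over a structure set;
a quasi-chemical variant ε = −log[f/(p⊗p)] is available behind a flag.
The packaged 20×20 table (`data/synthetic_contact_potential.txt`) is
computed once from this package's own synthetic toy structures
(`fixtures.make_statpot_structure_set`) — it has the right algebraic
properties but does not claim PDB statistics; users with a curated
structure set should supply their own table through
`sidechain_contact_counts`/`statistical_potential` or the text importer.

Projection evaluates the tensor at concrete sequences:
J_ij = J_ij(σ_i^A, σ_j^B). For identical chains the trans matrix *is* the
cis matrix; for heterophilic pairs the tensor is evaluated at the two
sequences through the shared family numbering. Normalization divides by
the RMS of the off-diagonal elements (the mean is taken over all pairs,
not only contact-forming ones — the simpler reading, fixed once). No APC
or top-N filtering is applied to the couplings, deliberately: every pair
interacts with its projected matrix element.

Alignment handling: projection keeps exactly the columns where the
reference row has no gap; redundancy filtering is a greedy keep-first pass
discarding any sequence whose identity to an already-kept one exceeds 90%.
Identity is computed over all columns with gap==gap counting as a match
(the simplest deterministic convention; stated so tests are exact). The
greedy filter is order-dependent by construction. An optional per-sequence
weight vector is accepted for forward compatibility with soft reweighting
but is unused by the hard filter.

## Sampling

Moves: single-dihedral flips (uniform perturbation up to ±30° by default,
rotating the smaller chain segment), multi-flips of 2–5 consecutive
dihedrals, pivots (uniform ±180° rotation of the downstream segment), and
rigid rototranslations of one chain. All act on torsions or rigid-body
coordinates, so the recorded bond geometry is preserved to machine
precision — verified after 10⁵-move runs at 10⁻⁶ tolerance. Proposals are
symmetric, so Metropolis acceptance min(1, e^{−ΔE/T}) (k_B = 1) satisfies
detailed balance; infinite-energy trials are always rejected.
Rototranslation of contact-connected chain *groups* is implemented but off
by default: selecting the moved group from the instantaneous contact graph
is not exactly proposal-symmetric, and the validation suite depends on
clean detailed balance.

Annealing from a fresh build runs at T = 10⁻³ with the infinite hard core
replaced by a finite per-violation penalty (1000 per overlapping pair),
so Metropolis can relax a clashed random placement downhill; step sizes
adapt toward 30–50% acceptance during this stage only and are frozen in
production. Parallel tempering attempts adjacent-pair swaps every 1000
steps (acceptance min(1, exp((β_i−β_j)(E_i−E_j)))), alternating even/odd
pairs between rounds. Umbrella production multiplies the trans contact
energy by k ∈ (0,1] and records the raw trans energy with every snapshot;
equilibrium averages are recovered with weights ∝ exp(−β(1−k)E_trans^raw),
normalized per trajectory (single-k reweighting only; no multi-k WHAM/MBAR
combination, matching the intended usage).

## Observables

A configuration is *dimeric* if any inter-chain SC pair within R has a
negative (attractive) energy contribution — a single contact suffices.
The dissociation constant of two identical chains in volume V is
k_D = 2(1−f)²/(f·N_A·V). The prefactor 2 (rather than the textbook 4 for
indistinguishable partners) is pinned by requiring the relation to
reproduce the reference triple (k_D = 166 μM, f = 0.3, V = 3.2×10⁴ nm³):
the prefactor-4 form gives f ≈ 0.42 at that k_D and volume. A temperature
calibration utility scans simulated f_B(T) and interpolates the T whose
bound fraction matches a target (e.g. one implied by an experimental k_D);
no calibration temperature is hard-coded.

Clustering uses average-linkage hierarchical clustering on pairwise CA
RMSD (optimal superposition), minimizing over the A↔B chain relabeling for
identical-sequence dimers; populations are summed snapshot weights and
representatives are weighted medoids. RMSF superposes snapshots onto an
iteratively refined weighted mean structure before measuring per-CA
deviations. Contact maps are weighted probabilities of SC–SC proximity
over concatenated residue indices (intra-chain quadrants symmetric by
construction). Specific heat is the energy-fluctuation estimator
(⟨E²⟩−⟨E⟩²)/T². Contact clusters on probability maps, where needed, are
8-neighbor connected components above a threshold — a convention, exposed
rather than asserted.

## Synthetic data and what the tests show

The fixtures module generates every input the validation needs: alignments
Gibbs-sampled from planted Potts models (one independent vectorized chain
per sequence, burn-in 100 sweeps — cross-checked against exact state
enumeration at L = 3), ideal-geometry toy chains built by
internal-coordinate extension at the α/β/extended motif dihedrals, an
analytic two-level system with closed-form occupancy and Schottky specific
heat, and miniature two-chain dimers with hand-set trans couplings. The
standard inference benchmark uses L = 6, q = 4, 3000 sequences and five
planted couplings of strength 1.5 — large enough that recovery is
information-limited rather than optimizer-limited, small enough to run in
seconds. Dimer validation uses 3-residue chains in a 4-nm box with a
single trans coupling of 3, sampled for ~6×10⁴ steps: far below
production scale, chosen so the bound and unbound states are both visited
many times.

These fixtures emulate the *statistical structure* of the real problem
(couplings detectable above noise, two-state binding equilibria, exact
Boltzmann references), not its scale or realism: toy alignments have no
phylogenetic correlation or gap structure, toy chains have no excluded-
volume frustration worth speaking of, and box sizes give millimolar-scale
effective concentrations. Passing tests therefore certify the machinery —
estimators, samplers, gradients, bookkeeping — not the biological accuracy
of any particular family model. Production use at family scale (alignments
of ~10⁴ sequences, 100-residue domains, 10⁹-step trajectories) is a
cluster-time question, not a code-path question.

## Numerical choices and limitations

* Dihedrals follow the standard sign convention (checked against two
  independent structural-bioinformatics libraries); undefined terminal
  torsions are NaN and skipped by the bias term. Collinear atom triples
  return NaN rather than raising.
* The contact step function is inclusive at r = R; energies are recomputed
  from scratch at every step (no incremental updates), so reproducibility
  is exact at toy sizes at the cost of O(n²) per step.
* L-BFGS convergence is declared at max-gradient 10⁻⁴ (tightenable);
  non-convergence raises with the final gradient norm attached.
* Umbrella weights are computed in log space with a max-shift, so large
  |E_trans| cannot overflow.
* The greedy redundancy filter is O(n²) in kept sequences and
  order-dependent; at Pfam scale a clustering-based dedup would be
  preferable.
* Identity of the fit at q = 21 with big L is compute-bound in pure
  numpy; the per-site conditional structure would parallelize readily if
  needed.
* Hard walls mean the "volume" entering k_D is the geometric box volume;
  no correction is made for the excluded shell near the walls.
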