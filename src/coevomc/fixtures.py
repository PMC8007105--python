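"""Synthetic inputs: Potts-sampled alignments with planted couplings, toy
chains with ideal geometry, analytic two-level systems, and miniature
dimers.

Everything here is seeded and reproducible, needs no network access, and is
first-class tested code: the generators define the conditions under which
the inference and sampling machinery is validated (known couplings in,
recovered couplings out; exact Boltzmann observables in, sampled ones out).
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Callable, Sequence

import numpy as np

from . import _geometry as geom
from .alignment import MSA
from .cgmodel import BoxSpec, CGChain, CGSystem
from .coevolution import CouplingMatrix, PottsParameters
from .energetics import DihedralPropensity, EnergyParams, dihedral_energy_from_angles


# ---------------------------------------------------------------------------
# Potts-sampled alignments

@dataclasses.dataclass
class SyntheticPottsSpec:
    """A planted Potts model and the sampling schedule for drawing from it.

    ``coupled_pairs`` are (site_i, site_k, strength) triples; each planted
    coupling is ferromagnetic, J_{IK}(a,b) = strength·δ_ab, unless
    ``coupling_style`` is "random" (seeded Gaussian blocks of that scale).
    One independent Gibbs chain is run per output sequence, for
    ``burn_in + thinning`` full sweeps.
    """

    L: int = 6
    q: int = 4
    coupled_pairs: Sequence[tuple[int, int, float]] = ()
    field_strength: float = 0.0
    n_sequences: int = 1000
    burn_in: int = 100
    thinning: int = 10
    seed: int = 0
    coupling_style: str = "ferromagnetic"

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("need at least one sequence")
        seen = set()
        for i, k, _ in self.coupled_pairs:
            if not (0 <= i < self.L and 0 <= k < self.L) or i == k:
                raise ValueError(f"invalid coupled pair ({i}, {k})")
            key = (min(i, k), max(i, k))
            if key in seen:
                raise ValueError(f"duplicate coupled pair {key}")
            seen.add(key)

    def parameters(self) -> PottsParameters:
        """The planted ground-truth model."""
        rng = np.random.default_rng(self.seed)
        h = (
            self.field_strength * rng.normal(size=(self.L, self.q))
            if self.field_strength > 0
            else np.zeros((self.L, self.q))
        )
        J = np.zeros((self.L, self.L, self.q, self.q))
        for i, k, s in self.coupled_pairs:
            if self.coupling_style == "ferromagnetic":
                block = s * np.eye(self.q)
            elif self.coupling_style == "random":
                block = s * rng.normal(size=(self.q, self.q))
            else:
                raise ValueError(f"unknown coupling style {self.coupling_style!r}")
            J[i, k] = block
            J[k, i] = block.T
        return PottsParameters(h, J)


def sample_potts_alignment(spec: SyntheticPottsSpec) -> MSA:
    """Draw an alignment by single-site Gibbs sampling of the planted model.

    Runs ``n_sequences`` independent chains in parallel (vectorized over
    sequences); each chain does ``burn_in + thinning`` sweeps from a
    uniform random start. States 0..q-1 are encoded with the first q
    letters of the amino-acid alphabet, so ``msa.encoded()`` returns
    exactly the sampled state matrix.
    """
    params = spec.parameters()
    h, J = params.h, params.J
    rng = np.random.default_rng(spec.seed + 1)
    n, L, q = spec.n_sequences, spec.L, spec.q
    X = rng.integers(0, q, size=(n, L))
    sweeps = spec.burn_in + spec.thinning
    rows = np.arange(n)
    for _ in range(sweeps):
        for I in range(L):
            logits = np.tile(h[I], (n, 1))
            for K in range(L):
                if K != I:
                    logits += J[I, K][:, X[:, K]].T
            gumbel = rng.gumbel(size=(n, q))
            X[:, I] = np.argmax(logits + gumbel, axis=1)
    return MSA.from_encoded(X)


def enumerate_potts_distribution(
    params: PottsParameters,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact state enumeration oracle for small models (q^L states).

    Returns (states, probabilities); feasible for L ≤ 8 with small q.
    """
    L, q = params.L, params.q
    if q**L > 2_000_000:
        raise ValueError("state space too large to enumerate")
    states = np.array(list(itertools.product(range(q), repeat=L)), dtype=int)
    energy = params.h[np.arange(L), states].sum(axis=1)
    iu, ku = np.triu_indices(L, k=1)
    for i, k in zip(iu, ku):
        energy = energy + params.J[i, k][states[:, i], states[:, k]]
    w = np.exp(energy - energy.max())
    return states, w / w.sum()


# ---------------------------------------------------------------------------
# toy chains with ideal geometry

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_CA_SC = 2.40
_ANGLE_N_CA_C = math.radians(111.0)
_ANGLE_CA_C_N = math.radians(116.6)
_ANGLE_C_N_CA = math.radians(121.7)
_ANGLE_N_CA_SC = math.radians(110.5)
_TORSION_SC = math.radians(120.0)  # improper C(i)-N(i)-CA(i)-SC
_OMEGA = math.pi  # trans peptide bond

MOTIF_DIHEDRALS = {
    "helix": (-63.0, -44.0),
    "strand": (-105.0, -140.0),
    "coil": (-150.0, 150.0),
}


def make_toy_chain(
    n_residues: int,
    motif: str = "helix",
    sequence: str | None = None,
) -> CGChain:
    """Ideal-geometry chain with every (φ, ψ) at the motif's values.

    Motifs: "helix" (−63°, −44°), "strand" (−105°, −140°), "coil"
    (extended, −150°/150°). The construction is exact: the returned
    chain's backbone dihedrals reproduce the motif values to numerical
    precision and the chain is free of hard-core clashes.
    """
    if n_residues < 2:
        raise ValueError("toy chains need >= 2 residues")
    if motif not in MOTIF_DIHEDRALS:
        raise ValueError(f"unknown motif {motif!r}")
    phi, psi = (math.radians(a) for a in MOTIF_DIHEDRALS[motif])
    if sequence is None:
        sequence = "A" * n_residues
    if len(sequence) != n_residues:
        raise ValueError("sequence length mismatch")

    N = np.zeros((n_residues, 3))
    CA = np.zeros((n_residues, 3))
    C = np.zeros((n_residues, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_BOND_N_CA, 0.0, 0.0)
    C[0] = CA[0] + _BOND_CA_C * np.array(
        [-math.cos(_ANGLE_N_CA_C), math.sin(_ANGLE_N_CA_C), 0.0]
    )
    for i in range(1, n_residues):
        N[i] = geom.place_atom(
            N[i - 1], CA[i - 1], C[i - 1], _BOND_C_N, _ANGLE_CA_C_N, psi
        )
        CA[i] = geom.place_atom(
            CA[i - 1], C[i - 1], N[i], _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA
        )
        C[i] = geom.place_atom(
            C[i - 1], N[i], CA[i], _BOND_CA_C, _ANGLE_N_CA_C, phi
        )
    coords = np.zeros((n_residues, 4, 3))
    coords[:, 0] = N
    coords[:, 1] = CA
    coords[:, 2] = C
    for i in range(n_residues):
        coords[i, 3] = geom.place_atom(
            C[i], N[i], CA[i], _BOND_CA_SC, _ANGLE_N_CA_SC, _TORSION_SC
        )
    chain = CGChain(sequence, coords)
    return chain


def make_statpot_structure_set(
    n_structures: int = 60,
    n_residues: int = 40,
    seed: int = 2024,
) -> list[CGChain]:
    """Deterministic toy structure set behind the packaged 20×20 potential.

    Random-sequence chains cycling through the three motifs; purely
    synthetic, so the resulting potential has the right algebraic shape
    (symmetric, finite, frequency-derived) without claiming PDB statistics.
    """
    rng = np.random.default_rng(seed)
    from .alphabet import AMINO_ACIDS

    motifs = ("helix", "strand", "coil")
    chains = []
    for s in range(n_structures):
        seq = "".join(
            AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), n_residues)
        )
        chains.append(make_toy_chain(n_residues, motifs[s % 3], seq))
    return chains


# ---------------------------------------------------------------------------
# analytic two-level toy

@dataclasses.dataclass
class TwoLevelSystem:
    """Two states {0, 1} with energies {0, ΔE} and exact observables.

    The ground truth for Metropolis, parallel-tempering and specific-heat
    checks: excited-state occupancy f(T) = e^{−ΔE/T}/(1 + e^{−ΔE/T}) and
    Schottky specific heat C(T) = (ΔE/T)²·x/(1+x)² with x = e^{−ΔE/T}.
    """

    delta_e: float = 1.0

    def energy(self, state: int) -> float:
        return self.delta_e * state

    def propose(self, state: int, rng: np.random.Generator) -> int:
        return 1 - state

    def exact_occupancy(self, T: float) -> float:
        x = math.exp(-self.delta_e / T)
        return x / (1.0 + x)

    def exact_specific_heat(self, T: float) -> float:
        x = math.exp(-self.delta_e / T)
        return (self.delta_e / T) ** 2 * x / (1.0 + x) ** 2


# ---------------------------------------------------------------------------
# single-dihedral toy (continuous state, analytic Boltzmann density)

def single_dihedral_energy(
    params: EnergyParams | None = None,
    w_alpha: float = 1.0,
    w_beta: float = 0.0,
) -> Callable[[float], float]:
    """Energy of one free φ dihedral under the Gaussian propensity bias.

    Returns a callable E(φ_degrees); the analytic Boltzmann density on the
    circle is ∝ exp(−E(φ)/T), which tests integrate numerically.
    """
    params = params or EnergyParams()
    prop = DihedralPropensity(np.array([w_alpha]), np.array([w_beta]))

    def energy(phi_deg: float) -> float:
        angles = np.array([[phi_deg, np.nan]])
        return dihedral_energy_from_angles(angles, prop, params)

    return energy


# ---------------------------------------------------------------------------
# miniature dimers

def make_toy_dimer(
    n_residues: int = 3,
    separation: float = 12.0,
    trans_coupling: float = 2.0,
    pattern: str = "single",
    box_size_nm: float = 5.0,
    motif: str = "strand",
) -> tuple[CGSystem, CouplingMatrix, CouplingMatrix]:
    """Two identical toy chains in a small box with hand-set trans couplings.

    Returns (system, cis matrix, trans matrix). The cis couplings are zero
    (short chains have no |i−j| ≥ 3 pairs to speak of); the trans matrix
    has either one coupled pair ("single": terminal residues) or all pairs
    coupled ("uniform"). Positive coupling with ε₀ = −1 is attractive.
    Chains start ``separation`` Å apart along x.
    """
    chain = make_toy_chain(n_residues, motif=motif)
    a = chain.copy()
    b = chain.copy()
    b.coords = b.coords + np.array([separation, 0.0, 0.0])
    center = np.concatenate([a.flat_coords(), b.flat_coords()]).mean(axis=0)
    a.coords -= center
    b.coords -= center
    system = CGSystem([a, b], BoxSpec("cube", box_size_nm))

    cis = CouplingMatrix(np.zeros((n_residues, n_residues)))
    if pattern == "single":
        J = np.zeros((n_residues, n_residues))
        J[0, 0] = trans_coupling
    elif pattern == "uniform":
        J = np.full((n_residues, n_residues), trans_coupling)
    else:
        raise ValueError(f"unknown coupling pattern {pattern!r}")
    trans = CouplingMatrix(J)
    return system, cis, trans
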