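"""The coarse-grained interaction energy.

The total energy of a configuration is the sum of

* a hard-core repulsion (infinite below R_HC = 2 Å) acting between all bead
  pairs except directly bonded neighbors and beads of the same residue, plus
  hard box walls;
* a step-function contact attraction ε₀·J[i,j] between side-chain beads
  within R = 8.5 Å, using the cis coupling matrix within a chain
  (|i−j| ≥ 3) and the trans matrix between chains, the latter multiplied by
  the umbrella rescale factor k ∈ (0,1];
* a backbone-dihedral bias: a negative sum of propensity-weighted Gaussian
  wells centered at ideal α and β dihedral values;
* optional infinite square-well restraints between CA beads (e.g. the
  calcium-rigidified inter-domain pairs of cadherins).

Energies are in model units with k_B = 1; ε₀ = −1 makes positive projected
couplings attractive (negative contribution), and a contact is called
"attractive" iff its contribution is negative.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from ._geometry import wrap_angle_deg
from .cgmodel import C, CA, CGChain, CGSystem, backbone_dihedrals
from .cgmodel import N as N_BEAD
from .coevolution import CouplingMatrix

INF = math.inf


@dataclasses.dataclass
class EnergyParams:
    """Model parameters with their standard defaults.

    R and R_HC in Å; ε_dih in energy units; dihedral centers and widths in
    degrees; k is the trans-interaction rescale factor of umbrella runs.
    """

    R: float = 8.5
    R_HC: float = 2.0
    eps0: float = -1.0
    eps_dih: float = 90.0
    phi0_alpha: float = -63.0
    psi0_alpha: float = -44.0
    phi0_beta: float = -105.0
    psi0_beta: float = -140.0
    sigma_alpha: float = 30.0
    sigma_beta: float = 40.0
    k_trans: float = 1.0
    min_sequence_separation: int = 3

    def __post_init__(self) -> None:
        if not self.R > self.R_HC > 0:
            raise ValueError("need R > R_HC > 0")
        if not 0 <= self.k_trans <= 1:
            raise ValueError("trans rescale factor k must lie in [0, 1]")


@dataclasses.dataclass
class DihedralPropensity:
    """Per-residue α/β propensities (e.g. parsed from PsiPred output)."""

    w_alpha: np.ndarray
    w_beta: np.ndarray

    def __post_init__(self) -> None:
        self.w_alpha = np.asarray(self.w_alpha, dtype=float)
        self.w_beta = np.asarray(self.w_beta, dtype=float)
        if self.w_alpha.shape != self.w_beta.shape:
            raise ValueError("w_alpha and w_beta must have equal length")
        if np.any(~np.isfinite(self.w_alpha)) or np.any(~np.isfinite(self.w_beta)):
            raise ValueError("propensities must be finite")
        if np.any(self.w_alpha < 0) or np.any(self.w_beta < 0):
            raise ValueError("propensities must be nonnegative")

    def __len__(self) -> int:
        return len(self.w_alpha)

    @classmethod
    def uniform(cls, n: int, w_alpha: float = 0.0, w_beta: float = 0.0):
        return cls(np.full(n, w_alpha), np.full(n, w_beta))

    @classmethod
    def from_table(cls, path) -> "DihedralPropensity":
        """Read a 3-column text table: residue index, w_alpha, w_beta."""
        data = np.loadtxt(path, ndmin=2)
        order = np.argsort(data[:, 0])
        return cls(data[order, 1], data[order, 2])

    def to_table(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# residue  w_alpha  w_beta\n")
            for i, (a, b) in enumerate(zip(self.w_alpha, self.w_beta)):
                fh.write(f"{i:6d} {a:8.4f} {b:8.4f}\n")


@dataclasses.dataclass(frozen=True)
class Restraint:
    """Infinite square well on a CA-CA distance (Å)."""

    chain_i: int
    res_i: int
    chain_j: int
    res_j: int
    r_min: float
    r_max: float

    def __post_init__(self) -> None:
        if not self.r_min < self.r_max:
            raise ValueError("restraint needs r_min < r_max")


RestraintSet = Sequence[Restraint]


@dataclasses.dataclass
class EnergyBreakdown:
    """Per-term decomposition of one configuration's energy.

    ``total`` sums the finite terms only; any infinite term marks the
    configuration as forbidden (move rejection).
    """

    hardcore: float
    contact_cis: float
    contact_trans_raw: float
    contact_trans: float
    dihedral: float
    restraint: float

    @property
    def total(self) -> float:
        if self.hardcore == INF or self.restraint == INF:
            return INF
        return self.contact_cis + self.contact_trans + self.dihedral

    @property
    def forbidden(self) -> bool:
        return self.hardcore == INF or self.restraint == INF


# ---------------------------------------------------------------------------
# term evaluators

def _pairwise_d2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)


def hardcore_check(system: CGSystem, params: EnergyParams) -> bool:
    """True iff no forbidden bead overlap exists and all beads are in the box.

    Excluded from the overlap check: pairs of beads within one residue and
    the directly bonded C(i)-N(i+1) pair.
    """
    r2 = params.R_HC**2
    for chain in system.chains:
        if not system.box.contains(chain.flat_coords()):
            return False
    chains = system.chains
    for ci in range(len(chains)):
        a = chains[ci].flat_coords()
        # intra-chain
        d2 = _pairwise_d2(a, a)
        n = chains[ci].n_residues
        res_of = np.repeat(np.arange(n), 4)
        bead_of = np.tile(np.arange(4), n)
        same_res = res_of[:, None] == res_of[None, :]
        bonded = (
            (res_of[:, None] + 1 == res_of[None, :])
            & (bead_of[:, None] == C)
            & (bead_of[None, :] == N_BEAD)
        )
        excluded = same_res | bonded | bonded.T
        if np.any(d2[~excluded] < r2):
            return False
        for cj in range(ci + 1, len(chains)):
            if np.min(_pairwise_d2(a, chains[cj].flat_coords())) < r2:
                return False
    return True


def count_hardcore_violations(system: CGSystem, params: EnergyParams) -> int:
    """Number of overlapping non-excluded bead pairs plus out-of-box beads.

    Used as a finite clash penalty during annealing, where the infinite
    hard core would make Metropolis undefined from a clashed start.
    """
    r2 = params.R_HC**2
    count = 0
    chains = system.chains
    for ci in range(len(chains)):
        a = chains[ci].flat_coords()
        if system.box.shape == "cube":
            half = system.box.size_angstrom / 2.0
            count += int(np.sum(np.any(np.abs(a) > half, axis=1)))
        else:
            count += int(np.sum(np.sum(a**2, axis=1) > system.box.size_angstrom**2))
        d2 = _pairwise_d2(a, a)
        n = chains[ci].n_residues
        res_of = np.repeat(np.arange(n), 4)
        bead_of = np.tile(np.arange(4), n)
        same_res = res_of[:, None] == res_of[None, :]
        bonded = (
            (res_of[:, None] + 1 == res_of[None, :])
            & (bead_of[:, None] == C)
            & (bead_of[None, :] == N_BEAD)
        )
        excluded = same_res | bonded | bonded.T
        iu = np.triu_indices(len(a), k=1)
        viol = (d2 < r2) & ~excluded
        count += int(np.sum(viol[iu]))
        for cj in range(ci + 1, len(chains)):
            count += int(
                np.sum(_pairwise_d2(a, chains[cj].flat_coords()) < r2)
            )
    return count


def contact_energy(
    system: CGSystem,
    cm_cis: Sequence[CouplingMatrix] | CouplingMatrix,
    cm_trans: CouplingMatrix | None,
    params: EnergyParams,
) -> tuple[float, float]:
    """Step-function contact energy: (cis, trans_raw).

    The trans term is returned unrescaled; multiply by ``params.k_trans``
    for the energy that enters sampling. ``cm_cis`` may be one matrix
    (shared by all chains) or one per chain; ``cm_trans`` applies to every
    chain pair.
    """
    chains = system.chains
    if isinstance(cm_cis, CouplingMatrix):
        cis_list = [cm_cis] * len(chains)
    else:
        cis_list = list(cm_cis)
    if len(cis_list) != len(chains):
        raise ValueError("need one cis coupling matrix per chain")

    R2 = params.R**2
    cis = 0.0
    for chain, cm in zip(chains, cis_list):
        n = chain.n_residues
        if cm.Jmat.shape != (n, n):
            raise ValueError(
                f"cis matrix shape {cm.Jmat.shape} != ({n},{n})"
            )
        d2 = _pairwise_d2(chain.sc_coords, chain.sc_coords)
        ii, jj = np.triu_indices(n, k=params.min_sequence_separation)
        mask = d2[ii, jj] <= R2
        cis += params.eps0 * float(np.sum(cm.Jmat[ii[mask], jj[mask]]))

    trans = 0.0
    if len(chains) > 1:
        if cm_trans is None:
            raise ValueError("multi-chain system needs a trans coupling matrix")
        for ci in range(len(chains)):
            for cj in range(ci + 1, len(chains)):
                na, nb = chains[ci].n_residues, chains[cj].n_residues
                if cm_trans.Jmat.shape != (na, nb):
                    raise ValueError(
                        f"trans matrix shape {cm_trans.Jmat.shape} != ({na},{nb})"
                    )
                d2 = _pairwise_d2(chains[ci].sc_coords, chains[cj].sc_coords)
                trans += params.eps0 * float(np.sum(cm_trans.Jmat[d2 <= R2]))
    return cis, trans


def dihedral_energy(
    chain: CGChain,
    prop: DihedralPropensity,
    params: EnergyParams,
) -> float:
    """Propensity-weighted Gaussian dihedral bias (negative at the wells).

    Each defined φ and ψ contributes
    −ε_dih·[w^α·exp(−Δ_α²/2σ_α²) + w^β·exp(−Δ_β²/2σ_β²)], with Δ the
    periodic difference to the α/β center for that dihedral type.
    """
    if len(prop) != chain.n_residues:
        raise ValueError(
            f"propensity table length {len(prop)} != {chain.n_residues} residues"
        )
    dih = backbone_dihedrals(chain)
    return dihedral_energy_from_angles(dih, prop, params)


def dihedral_energy_from_angles(
    dihedrals_deg: np.ndarray,
    prop: DihedralPropensity,
    params: EnergyParams,
) -> float:
    """Same bias evaluated on an (n, 2) array of (φ, ψ) in degrees."""
    phi = dihedrals_deg[:, 0]
    psi = dihedrals_deg[:, 1]
    e = 0.0
    for angles, c_alpha, c_beta in (
        (phi, params.phi0_alpha, params.phi0_beta),
        (psi, params.psi0_alpha, params.psi0_beta),
    ):
        ok = np.isfinite(angles)
        da = np.asarray(wrap_angle_deg(angles[ok] - c_alpha))
        db = np.asarray(wrap_angle_deg(angles[ok] - c_beta))
        e += float(np.sum(
            prop.w_alpha[ok] * np.exp(-(da**2) / (2 * params.sigma_alpha**2))
            + prop.w_beta[ok] * np.exp(-(db**2) / (2 * params.sigma_beta**2))
        ))
    return -params.eps_dih * e


def restraint_energy(system: CGSystem, restraints: RestraintSet) -> float:
    """0 if every restrained CA-CA distance is inside its well, else +inf."""
    for r in restraints:
        pi = system.chains[r.chain_i].coords[r.res_i, CA]
        pj = system.chains[r.chain_j].coords[r.res_j, CA]
        d = float(np.linalg.norm(pi - pj))
        if not (r.r_min <= d <= r.r_max):
            return INF
    return 0.0


def total_energy(
    system: CGSystem,
    cm_cis: Sequence[CouplingMatrix] | CouplingMatrix,
    cm_trans: CouplingMatrix | None = None,
    prop: DihedralPropensity | Sequence[DihedralPropensity] | None = None,
    restraints: RestraintSet = (),
    params: EnergyParams | None = None,
) -> EnergyBreakdown:
    """Assemble the full energy breakdown of a configuration."""
    params = params or EnergyParams()
    hc = 0.0 if hardcore_check(system, params) else INF
    cis, trans_raw = contact_energy(system, cm_cis, cm_trans, params)
    dih = 0.0
    if prop is not None:
        props = (
            [prop] * system.n_chains
            if isinstance(prop, DihedralPropensity)
            else list(prop)
        )
        for chain, p in zip(system.chains, props):
            dih += dihedral_energy(chain, p, params)
    restr = restraint_energy(system, restraints)
    return EnergyBreakdown(
        hardcore=hc,
        contact_cis=cis,
        contact_trans_raw=trans_raw,
        contact_trans=params.k_trans * trans_raw,
        dihedral=dih,
        restraint=restr,
    )


@dataclasses.dataclass
class EnergyModel:
    """Bundle of everything needed to score a system; callable closure.

    Used as the energy function handed to the samplers. ``k_trans`` on the
    params controls the umbrella rescaling of the trans term.
    """

    cm_cis: Sequence[CouplingMatrix] | CouplingMatrix
    cm_trans: CouplingMatrix | None = None
    prop: DihedralPropensity | Sequence[DihedralPropensity] | None = None
    restraints: RestraintSet = ()
    params: EnergyParams = dataclasses.field(default_factory=EnergyParams)

    def breakdown(self, system: CGSystem) -> EnergyBreakdown:
        return total_energy(
            system, self.cm_cis, self.cm_trans, self.prop,
            self.restraints, self.params,
        )

    def __call__(self, system: CGSystem) -> float:
        return self.breakdown(system).total

    def with_k(self, k: float) -> "EnergyModel":
        return dataclasses.replace(
            self, params=dataclasses.replace(self.params, k_trans=k)
        )
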