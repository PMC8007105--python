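"""From trajectories to reported quantities.

Umbrella reweighting turns a run with rescaled inter-chain interactions into
an equilibrium-weighted ensemble; from there the bound fraction, the
dissociation constant of a two-molecule box, contact-probability maps, RMSD
and per-residue fluctuations, specific heat, conformational clusters and
pairwise distance distributions are all weighted ensemble averages.

The dissociation constant of two identical chains in a box of volume V is

    k_D = 2 (1 − f)² / (f · N_A · V)

with f the fraction of dimeric (bound) conformations. A conformation is
dimeric if any inter-chain side-chain contact within the interaction range
is attractive (negative energy contribution).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.constants import Avogadro
from scipy.spatial.distance import squareform

from ._geometry import kabsch_rmsd
from .cgmodel import CA, CGChain, CGSystem, SC
from .coevolution import CouplingMatrix
from .energetics import EnergyParams
from .sampling import Trajectory

Snapshot = Sequence[np.ndarray]  # one (n,4,3) array per chain


@dataclasses.dataclass
class WeightedEnsemble:
    """Sampled snapshots with normalized statistical weights.

    ``normalization`` stores ⟨exp(−β(1−k)E_trans)⟩_k, the umbrella
    denominator (1 for an unrescaled run).
    """

    snapshots: list[Snapshot]
    weights: np.ndarray
    temperature: float = 1.0
    k_trans: float = 1.0
    normalization: float = 1.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.snapshots) != len(self.weights):
            raise ValueError("one weight per snapshot required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be positive")
        s = self.weights.sum()
        if not np.isclose(s, 1.0):
            raise ValueError("weights must sum to 1")

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshots)

    @classmethod
    def uniform(cls, snapshots: list[Snapshot], **kw) -> "WeightedEnsemble":
        n = len(snapshots)
        return cls(snapshots, np.full(n, 1.0 / n), **kw)


def reweight_umbrella(traj: Trajectory, beta: float | None = None) -> WeightedEnsemble:
    """Recover k = 1 equilibrium weights from a k-rescaled trajectory.

    weight(r) ∝ exp(−β(1−k)·E_trans_raw(r)); the normalization constant is
    the trajectory average of the same factor. A k = 1 trajectory gets
    exactly uniform weights.
    """
    if traj.n_snapshots == 0:
        raise ValueError("empty trajectory")
    if beta is None:
        beta = 1.0 / traj.temperature
    k = traj.k_trans
    if k == 1.0:
        factors = np.ones(traj.n_snapshots)
    else:
        if len(traj.trans_raw) != traj.n_snapshots:
            raise ValueError(
                "trajectory lacks raw trans-energy records; cannot reweight"
            )
        e_raw = traj.trans_raw_array()
        log_f = -beta * (1.0 - k) * e_raw
        log_f -= log_f.max()  # overflow guard; cancels in the ratio
        factors = np.exp(log_f)
    return WeightedEnsemble(
        list(traj.states),
        factors / factors.sum(),
        temperature=traj.temperature,
        k_trans=k,
        normalization=float(np.mean(factors)),
    )


# ---------------------------------------------------------------------------
# binding and the dissociation constant

def snapshot_is_bound(
    snapshot: Snapshot, cm_trans: CouplingMatrix, params: EnergyParams
) -> bool:
    """True iff any inter-chain SC pair within R is attractive."""
    if len(snapshot) < 2:
        raise ValueError("binding is defined for systems of >= 2 chains")
    for ci in range(len(snapshot)):
        for cj in range(ci + 1, len(snapshot)):
            a = snapshot[ci][:, SC, :]
            b = snapshot[cj][:, SC, :]
            d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
            contrib = params.eps0 * cm_trans.Jmat
            if np.any((d2 <= params.R**2) & (contrib < 0)):
                return True
    return False


def fraction_bound(
    ensemble: WeightedEnsemble,
    cm_trans: CouplingMatrix,
    params: EnergyParams | None = None,
) -> float:
    """Weighted fraction of dimeric snapshots."""
    params = params or EnergyParams()
    flags = np.array([
        snapshot_is_bound(s, cm_trans, params) for s in ensemble.snapshots
    ])
    return float(np.clip(np.sum(ensemble.weights[flags]), 0.0, 1.0))


def kd_from_fraction(f: float, volume_nm3: float) -> float:
    """Dissociation constant (molar) of two molecules in a box of V nm³."""
    if not 0 < f < 1:
        raise ValueError("bound fraction must lie strictly in (0, 1)")
    if volume_nm3 <= 0:
        raise ValueError("volume must be positive")
    v_liters = volume_nm3 * 1e-24
    return 2.0 * (1.0 - f) ** 2 / (f * Avogadro * v_liters)


def fraction_from_kd(kd_molar: float, volume_nm3: float) -> float:
    """Invert :func:`kd_from_fraction` for f on (0, 1).

    Solves 2(1−f)² = f·k_D·N_A·V, i.e. 2f² − (4 + c)f + 2 = 0 with
    c = k_D·N_A·V; the root below 1 is the physical one.
    """
    if kd_molar <= 0 or volume_nm3 <= 0:
        raise ValueError("k_D and volume must be positive")
    c = kd_molar * Avogadro * volume_nm3 * 1e-24
    b = 4.0 + c
    return (b - np.sqrt(b * b - 16.0)) / 4.0


def box_concentration(n_molecules: int, volume_nm3: float) -> float:
    """Molar concentration of n molecules in a box of V nm³."""
    return n_molecules / (Avogadro * volume_nm3 * 1e-24)


def calibrate_temperature(
    temperatures: Sequence[float],
    bound_fractions: Sequence[float],
    target_f: float,
) -> float:
    """Temperature at which the simulated f_B curve crosses a target value.

    Used to anchor the simulation temperature to an experimental k_D
    (through its implied bound fraction) by scanning T; linear
    interpolation between the two bracketing scan points.
    """
    T = np.asarray(temperatures, dtype=float)
    f = np.asarray(bound_fractions, dtype=float)
    order = np.argsort(T)
    T, f = T[order], f[order]
    crossings = np.nonzero(np.diff(np.sign(f - target_f)) != 0)[0]
    if len(crossings) == 0:
        raise ValueError("target bound fraction is outside the scanned range")
    i = crossings[0]
    t = (target_f - f[i]) / (f[i + 1] - f[i])
    return float(T[i] + t * (T[i + 1] - T[i]))


# ---------------------------------------------------------------------------
# contact maps

@dataclasses.dataclass
class ContactMap:
    """Residue-residue contact probabilities over concatenated chains.

    The diagonal blocks (lower-left, upper-right quadrants for a dimer)
    are the intra-chain maps; the off-diagonal block is the inter-chain
    map.
    """

    probabilities: np.ndarray
    chain_lengths: tuple[int, ...]

    def quadrant(self, i: int, j: int) -> np.ndarray:
        offsets = np.concatenate([[0], np.cumsum(self.chain_lengths)])
        return self.probabilities[
            offsets[i]:offsets[i + 1], offsets[j]:offsets[j + 1]
        ]


def contact_probability(
    ensemble: WeightedEnsemble, R: float = 8.5
) -> ContactMap:
    """Weighted probability that each residue pair's SC beads are within R."""
    first = ensemble.snapshots[0]
    lengths = tuple(c.shape[0] for c in first)
    total = sum(lengths)
    probs = np.zeros((total, total))
    for snap, w in zip(ensemble.snapshots, ensemble.weights):
        sc = np.concatenate([c[:, SC, :] for c in snap])
        d2 = np.sum((sc[:, None, :] - sc[None, :, :]) ** 2, axis=-1)
        probs += w * (d2 <= R * R)
    return ContactMap(probs, lengths)


# ---------------------------------------------------------------------------
# structural deviation and fluctuation

def _ca_matrix(obj) -> np.ndarray:
    if isinstance(obj, CGChain):
        return obj.ca_coords
    if isinstance(obj, CGSystem):
        return np.concatenate([c.ca_coords for c in obj.chains])
    if isinstance(obj, np.ndarray):
        return obj[:, CA, :] if obj.ndim == 3 else obj
    return np.concatenate([np.asarray(c)[:, CA, :] for c in obj])


def rmsd(conformation, reference, selection: str = "CA") -> float:
    """Minimal RMSD (coordinate units, Å) after optimal superposition."""
    if selection == "CA":
        x, y = _ca_matrix(conformation), _ca_matrix(reference)
    elif selection == "all":
        x = np.concatenate([np.asarray(c).reshape(-1, 3) for c in conformation])
        y = np.concatenate([np.asarray(c).reshape(-1, 3) for c in reference])
    else:
        raise ValueError(f"unknown selection {selection!r}")
    if x.shape != y.shape:
        raise ValueError(f"selection shapes differ: {x.shape} vs {y.shape}")
    return kabsch_rmsd(x, y)


def _superpose_onto(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Return x optimally superposed onto ref (both centered point sets)."""
    xc = x - x.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    C = xc.T @ rc
    U, _, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return xc @ R + ref.mean(axis=0)


def per_residue_fluctuations(ensemble: WeightedEnsemble) -> np.ndarray:
    """Weighted RMSF of each CA about its weighted mean position.

    Snapshots are iteratively superposed (CA selection) onto the running
    weighted mean structure before the fluctuations are measured, so rigid
    drift of the whole system does not count.
    """
    cas = [_ca_matrix(s) for s in ensemble.snapshots]
    w = ensemble.weights
    ref = cas[0]
    for _ in range(3):
        aligned = [_superpose_onto(x, ref) for x in cas]
        ref = np.sum(w[:, None, None] * np.stack(aligned), axis=0)
    aligned = np.stack([_superpose_onto(x, ref) for x in cas])
    mean = np.sum(w[:, None, None] * aligned, axis=0)
    dev2 = np.sum((aligned - mean) ** 2, axis=-1)
    return np.sqrt(np.sum(w[:, None] * dev2, axis=0))


def specific_heat(energies: np.ndarray, T: float, weights: np.ndarray | None = None) -> float:
    """C(T) = (⟨E²⟩ − ⟨E⟩²) / T² from an equilibrated energy series."""
    e = np.asarray(energies, dtype=float)
    if weights is None:
        mean = e.mean()
        var = np.mean((e - mean) ** 2)
    else:
        w = np.asarray(weights) / np.sum(weights)
        mean = np.sum(w * e)
        var = np.sum(w * (e - mean) ** 2)
    return float(var / T**2)


# ---------------------------------------------------------------------------
# clustering

@dataclasses.dataclass
class ConformationalCluster:
    members: np.ndarray
    population: float
    medoid: int


def _pair_rmsd_dimer_aware(a: Snapshot, b: Snapshot, identical: bool) -> float:
    x = np.concatenate([np.asarray(c)[:, CA, :] for c in a])
    y = np.concatenate([np.asarray(c)[:, CA, :] for c in b])
    r = kabsch_rmsd(x, y)
    if identical and len(b) == 2:
        y_sw = np.concatenate([np.asarray(b[1])[:, CA, :], np.asarray(b[0])[:, CA, :]])
        r = min(r, kabsch_rmsd(x, y_sw))
    return r


def cluster_conformations(
    ensemble: WeightedEnsemble,
    cutoff: float,
    identical_chains: bool = False,
) -> list[ConformationalCluster]:
    """Average-linkage hierarchical clustering on pairwise CA RMSD.

    For dimers of identical sequences the distance minimizes over the A↔B
    chain relabeling. Cluster populations are summed snapshot weights
    (they sum to 1); representatives are medoids (minimal weighted distance
    to the rest of the cluster). Clusters come back sorted by population.
    """
    n = ensemble.n_snapshots
    if n < 2:
        raise ValueError("clustering needs at least 2 snapshots")
    snaps = ensemble.snapshots
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = _pair_rmsd_dimer_aware(
                snaps[i], snaps[j], identical_chains
            )
    Z = linkage(squareform(dmat, checks=False), method="average")
    labels = fcluster(Z, t=cutoff, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        members = np.nonzero(labels == lab)[0]
        pop = float(np.sum(ensemble.weights[members]))
        sub = dmat[np.ix_(members, members)]
        wsub = ensemble.weights[members]
        medoid = members[int(np.argmin(sub @ wsub))]
        clusters.append(ConformationalCluster(members, pop, int(medoid)))
    clusters.sort(key=lambda c: -c.population)
    return clusters


# ---------------------------------------------------------------------------
# distance distributions

def pair_distance_distribution(
    ensemble: WeightedEnsemble,
    selection_a: Sequence[tuple[int, int]],
    selection_b: Sequence[tuple[int, int]],
    bins: int | np.ndarray = 50,
    bead: int = CA,
    range_: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted histogram of distances over all cross-pairs of two
    (chain, residue) selections. Returns (density histogram, bin edges)."""
    dists, wts = [], []
    for snap, w in zip(ensemble.snapshots, ensemble.weights):
        for ca, ra in selection_a:
            for cb, rb in selection_b:
                d = np.linalg.norm(
                    snap[ca][ra, bead] - snap[cb][rb, bead]
                )
                dists.append(d)
                wts.append(w)
    hist, edges = np.histogram(
        dists, bins=bins, range=range_, weights=wts, density=True
    )
    return hist, edges
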