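"""Metropolis Monte Carlo, parallel tempering and umbrella production runs.

All moves act on backbone dihedrals or rigid-body coordinates, so bond
lengths and angles are preserved exactly; proposal densities are symmetric
(uniform perturbations), so plain Metropolis acceptance min(1, e^{−ΔE/T})
satisfies detailed balance. k_B = 1 throughout: temperatures are energies.

The kernels are generic over a *state*: they only need an energy function,
a symmetric proposal function, and (for recording) a snapshot function.
Coarse-grained systems plug in through :func:`propose_move` and
:class:`~coevomc.energetics.EnergyModel`.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Any, Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .cgmodel import CGSystem, rotate_dihedral
from .energetics import EnergyModel, EnergyParams, count_hardcore_violations


# ---------------------------------------------------------------------------
# move set for CG systems

@dataclasses.dataclass
class MoveSet:
    """Weights and step sizes of the CG move repertoire.

    flip: uniform perturbation of one backbone dihedral (the smaller chain
    segment rotates); multi-flip: 2-5 consecutive dihedrals at once; pivot:
    large-angle rotation of the downstream segment about one dihedral;
    rigid: rototranslation of one whole chain. Group rototranslations of
    chains linked by inter-chain contacts can be enabled with
    ``group_moves`` (off by default: the group choice depends on the
    instantaneous contact graph, which breaks exact proposal symmetry).
    """

    w_flip: float = 1.0
    w_multiflip: float = 0.5
    w_pivot: float = 0.5
    w_rigid: float = 0.0
    max_flip_deg: float = 30.0
    max_translation: float = 2.0
    max_rigid_rotation_deg: float = 30.0
    multiflip_max: int = 5
    group_moves: bool = False
    group_cutoff: float = 8.5

    def __post_init__(self) -> None:
        w = np.array([self.w_flip, self.w_multiflip, self.w_pivot, self.w_rigid])
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("move weights must be nonnegative, not all zero")

    def weights(self) -> np.ndarray:
        w = np.array([self.w_flip, self.w_multiflip, self.w_pivot, self.w_rigid])
        return w / w.sum()

    def scaled(self, factor: float) -> "MoveSet":
        return dataclasses.replace(
            self,
            max_flip_deg=min(self.max_flip_deg * factor, 180.0),
            max_translation=self.max_translation * factor,
            max_rigid_rotation_deg=min(self.max_rigid_rotation_deg * factor, 180.0),
        )


def _rotatable_dihedrals(n_res: int) -> list[tuple[int, str]]:
    dih = [(i, "phi") for i in range(1, n_res)]
    dih += [(i, "psi") for i in range(n_res - 1)]
    dih.sort()
    return dih


def _rigid_move(
    coords: np.ndarray, moveset: MoveSet, rng: np.random.Generator
) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(
        rng.uniform(-moveset.max_rigid_rotation_deg, moveset.max_rigid_rotation_deg)
    )
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    shift = rng.uniform(-moveset.max_translation, moveset.max_translation, size=3)
    center = coords.reshape(-1, 3).mean(axis=0)
    return (coords - center) @ R.T + center + shift


def _contact_group(system: CGSystem, seed_chain: int, cutoff: float) -> list[int]:
    """Chains connected to seed_chain through inter-chain SC contacts."""
    n = system.n_chains
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            d2 = np.sum(
                (system.chains[i].sc_coords[:, None, :]
                 - system.chains[j].sc_coords[None, :, :]) ** 2,
                axis=-1,
            )
            adj[i, j] = adj[j, i] = bool(np.min(d2) <= cutoff**2)
    group, frontier = {seed_chain}, [seed_chain]
    while frontier:
        cur = frontier.pop()
        for other in np.nonzero(adj[cur])[0]:
            if other not in group:
                group.add(int(other))
                frontier.append(int(other))
    return sorted(group)


def propose_move(
    system: CGSystem, moveset: MoveSet, rng: np.random.Generator
) -> CGSystem:
    """Draw one symmetric trial move and return the trial configuration."""
    new = system.copy()
    ci = int(rng.integers(system.n_chains))
    chain = new.chains[ci]
    kinds = ("flip", "multiflip", "pivot", "rigid")
    kind = kinds[int(rng.choice(4, p=moveset.weights()))]
    dihedrals = _rotatable_dihedrals(chain.n_residues)
    if kind in ("flip", "multiflip", "pivot") and not dihedrals:
        kind = "rigid"

    if kind == "flip":
        i, which = dihedrals[int(rng.integers(len(dihedrals)))]
        delta = np.radians(rng.uniform(-moveset.max_flip_deg, moveset.max_flip_deg))
        chain.coords = rotate_dihedral(chain.coords, i, which, delta, "smaller")
    elif kind == "multiflip":
        m = int(rng.integers(2, moveset.multiflip_max + 1))
        start = int(rng.integers(len(dihedrals)))
        for i, which in dihedrals[start:start + m]:
            delta = np.radians(
                rng.uniform(-moveset.max_flip_deg, moveset.max_flip_deg)
            )
            chain.coords = rotate_dihedral(chain.coords, i, which, delta, "smaller")
    elif kind == "pivot":
        i, which = dihedrals[int(rng.integers(len(dihedrals)))]
        delta = rng.uniform(-math.pi, math.pi)
        chain.coords = rotate_dihedral(chain.coords, i, which, delta, "downstream")
    else:  # rigid
        members = (
            _contact_group(system, ci, moveset.group_cutoff)
            if moveset.group_moves and system.n_chains > 1
            else [ci]
        )
        stacked = np.concatenate(
            [new.chains[m].coords.reshape(-1, 3) for m in members]
        )
        moved = _rigid_move(stacked, moveset, rng)
        offset = 0
        for m in members:
            nb = new.chains[m].coords.reshape(-1, 3).shape[0]
            new.chains[m].coords = moved[offset:offset + nb].reshape(
                new.chains[m].coords.shape
            )
            offset += nb
    return new


# ---------------------------------------------------------------------------
# generic Metropolis kernel

def metropolis_step(
    state: Any,
    energy: Callable[[Any], float],
    propose: Callable[[Any, np.random.Generator], Any],
    T: float,
    rng: np.random.Generator,
    current_energy: float | None = None,
) -> tuple[Any, float, bool]:
    """One Metropolis update: returns (state, its energy, accepted?).

    Trials with infinite energy are always rejected; downhill trials are
    always accepted.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    e_old = energy(state) if current_energy is None else current_energy
    trial = propose(state, rng)
    e_new = energy(trial)
    if math.isinf(e_new):
        return state, e_old, False
    de = e_new - e_old
    if de <= 0 or rng.random() < math.exp(-de / T):
        return trial, e_new, True
    return state, e_old, False


@dataclasses.dataclass
class Trajectory:
    """Periodic snapshots of one MC run.

    ``states`` holds whatever the snapshot function returned (chain
    coordinate lists for CG systems); ``trans_raw`` holds the unrescaled
    inter-chain contact energy when an :class:`EnergyModel` drives the run,
    which is what umbrella reweighting needs.
    """

    steps: list[int] = dataclasses.field(default_factory=list)
    states: list[Any] = dataclasses.field(default_factory=list)
    energies: list[float] = dataclasses.field(default_factory=list)
    trans_raw: list[float] = dataclasses.field(default_factory=list)
    temperature: float = 1.0
    k_trans: float = 1.0
    acceptance: float = 0.0

    @property
    def n_snapshots(self) -> int:
        return len(self.steps)

    def energy_array(self) -> np.ndarray:
        return np.asarray(self.energies)

    def trans_raw_array(self) -> np.ndarray:
        return np.asarray(self.trans_raw)


def _snapshot_cg(system: CGSystem) -> list[np.ndarray]:
    return [c.coords.copy() for c in system.chains]


def run_mc(
    state: Any,
    energy: Callable[[Any], float],
    propose: Callable[[Any, np.random.Generator], Any],
    steps: int,
    T: float,
    rng: np.random.Generator,
    snapshot_every: int = 1000,
    snapshot: Callable[[Any], Any] | None = None,
    trans_raw: Callable[[Any], float] | None = None,
) -> tuple[Any, Trajectory]:
    """Run a fixed-temperature Metropolis chain, recording periodic snapshots."""
    if snapshot is None:
        snapshot = _snapshot_cg if isinstance(state, CGSystem) else (lambda s: s)
    traj = Trajectory(temperature=T)
    e = energy(state)
    accepted = 0
    for step in range(1, steps + 1):
        state, e, acc = metropolis_step(state, energy, propose, T, rng, e)
        accepted += acc
        if step % snapshot_every == 0:
            traj.steps.append(step)
            traj.states.append(snapshot(state))
            traj.energies.append(e)
            if trans_raw is not None:
                traj.trans_raw.append(trans_raw(state))
    traj.acceptance = accepted / max(steps, 1)
    return state, traj


def run_cg_mc(
    system: CGSystem,
    model: EnergyModel,
    moveset: MoveSet,
    steps: int,
    T: float,
    rng: np.random.Generator,
    snapshot_every: int = 1000,
) -> tuple[CGSystem, Trajectory]:
    """Convenience wrapper wiring a CG system and its energy model into
    :func:`run_mc`, recording the raw trans energy at each snapshot."""
    traj_state, traj = run_mc(
        system,
        model,
        lambda s, r: propose_move(s, moveset, r),
        steps,
        T,
        rng,
        snapshot_every=snapshot_every,
        snapshot=_snapshot_cg,
        trans_raw=lambda s: model.breakdown(s).contact_trans_raw,
    )
    traj.k_trans = model.params.k_trans
    return traj_state, traj


# ---------------------------------------------------------------------------
# annealing initialization

class InitializationError(RuntimeError):
    pass


def anneal_initialize(
    system: CGSystem,
    model: EnergyModel,
    moveset: MoveSet | None = None,
    steps: int = 20000,
    T: float = 1e-3,
    rng: np.random.Generator | None = None,
    clash_penalty: float = 1000.0,
    adapt_every: int = 500,
) -> CGSystem:
    """Low-temperature run that removes steric clashes from a fresh build.

    The infinite hard core is replaced by a finite per-violation penalty so
    Metropolis can relax a clashed start downhill; at T = 10⁻³ the dynamics
    is quasi-greedy. Step sizes adapt toward 30-50% acceptance during this
    stage only. Raises if clashes survive the step budget.
    """
    rng = np.random.default_rng() if rng is None else rng
    moveset = moveset or MoveSet(w_rigid=0.5)

    def soft_energy(s: CGSystem) -> float:
        b = model.breakdown(s)
        pen = clash_penalty * count_hardcore_violations(s, model.params)
        if b.restraint == float("inf"):
            pen += clash_penalty
        return b.contact_cis + b.contact_trans + b.dihedral + pen

    state = system.copy()
    e = soft_energy(state)
    accepted_window = 0
    for step in range(1, steps + 1):
        state, e, acc = metropolis_step(
            state, soft_energy,
            lambda s, r: propose_move(s, moveset, r),
            T, rng, e,
        )
        accepted_window += acc
        if step % adapt_every == 0:
            rate = accepted_window / adapt_every
            accepted_window = 0
            if rate < 0.3:
                moveset = moveset.scaled(0.7)
            elif rate > 0.5:
                moveset = moveset.scaled(1.3)
            if count_hardcore_violations(state, model.params) == 0 and step >= steps // 4:
                break
    if count_hardcore_violations(state, model.params) != 0:
        raise InitializationError(
            f"steric clashes remain after {steps} annealing steps"
        )
    return state


# ---------------------------------------------------------------------------
# parallel tempering

@dataclasses.dataclass
class PTConfig:
    """Temperature ladder and exchange schedule for replica exchange."""

    ladder: Sequence[float]
    exchange_interval: int = 1000
    steps: int = 100000
    snapshot_every: int = 1000

    def __post_init__(self) -> None:
        ladder = list(self.ladder)
        if any(t2 < t1 for t1, t2 in zip(ladder, ladder[1:])):
            raise ValueError("temperature ladder must be ascending")
        if self.exchange_interval < 1:
            raise ValueError("exchange interval must be >= 1")


@dataclasses.dataclass
class PTResult:
    trajectories: list[Trajectory]
    swap_attempts: int = 0
    swap_accepts: int = 0

    @property
    def swap_acceptance(self) -> float:
        return self.swap_accepts / max(self.swap_attempts, 1)


def run_parallel_tempering(
    states: Sequence[Any],
    config: PTConfig,
    energy: Callable[[Any], float],
    propose: Callable[[Any, np.random.Generator], Any],
    rng: np.random.Generator,
    snapshot: Callable[[Any], Any] | None = None,
) -> PTResult:
    """Replica exchange: independent Metropolis chains at each ladder
    temperature, with adjacent-pair swaps every ``exchange_interval`` steps.

    Swap of replicas at (T_i, T_j) is accepted with probability
    min(1, exp((β_i − β_j)(E_i − E_j))); even/odd adjacent pairs alternate
    between exchange rounds. Snapshots are indexed by temperature slot. A
    single-temperature ladder degenerates to a plain MC run.
    """
    ladder = list(config.ladder)
    if len(states) != len(ladder):
        raise ValueError("need one starting state per ladder temperature")
    if snapshot is None:
        snapshot = (
            _snapshot_cg if states and isinstance(states[0], CGSystem)
            else (lambda s: s)
        )
    n = len(ladder)
    states = [s.copy() if hasattr(s, "copy") else s for s in states]
    energies = [energy(s) for s in states]
    result = PTResult([Trajectory(temperature=t) for t in ladder])
    parity = 0
    for step in range(1, config.steps + 1):
        for t in range(n):
            states[t], energies[t], _ = metropolis_step(
                states[t], energy, propose, ladder[t], rng, energies[t]
            )
        if step % config.exchange_interval == 0 and n > 1:
            for i in range(parity, n - 1, 2):
                bi, bj = 1.0 / ladder[i], 1.0 / ladder[i + 1]
                result.swap_attempts += 1
                ln_p = (bi - bj) * (energies[i] - energies[i + 1])
                if ln_p >= 0 or rng.random() < math.exp(ln_p):
                    states[i], states[i + 1] = states[i + 1], states[i]
                    energies[i], energies[i + 1] = energies[i + 1], energies[i]
                    result.swap_accepts += 1
            parity = 1 - parity
        if step % config.snapshot_every == 0:
            for t in range(n):
                traj = result.trajectories[t]
                traj.steps.append(step)
                traj.states.append(snapshot(states[t]))
                traj.energies.append(energies[t])
    return result


# ---------------------------------------------------------------------------
# umbrella production

def run_umbrella(
    system: CGSystem,
    model: EnergyModel,
    k_values: Sequence[float],
    steps: int,
    T: float,
    rng: np.random.Generator,
    moveset: MoveSet | None = None,
    snapshot_every: int = 1000,
) -> dict[float, Trajectory]:
    """Production runs with the trans interaction rescaled by each k.

    Each trajectory stores the *raw* inter-chain energy alongside the
    sampled configurations; umbrella reweighting multiplies snapshot
    weights by exp(−β(1−k)E_trans_raw) to recover k = 1 equilibrium
    averages a posteriori.
    """
    moveset = moveset or MoveSet(w_rigid=1.0)
    out: dict[float, Trajectory] = {}
    for k in k_values:
        if not 0 <= k <= 1:
            raise ValueError("each k must lie in [0, 1]")
        model_k = model.with_k(k)
        _, traj = run_cg_mc(
            system.copy(), model_k, moveset, steps, T, rng,
            snapshot_every=snapshot_every,
        )
        out[k] = traj
    return out
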