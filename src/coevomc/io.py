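"""Single-file HDF5 containers for fitted models, coupling matrices,
systems and trajectories. Every container echoes the resolved run
configuration (JSON) and the seed that produced it."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np

from .cgmodel import BoxSpec, CGChain, CGSystem
from .coevolution import CouplingMatrix, PottsParameters
from .sampling import Trajectory


def _write_meta(g: h5py.Group | h5py.File, config: dict[str, Any] | None) -> None:
    if config is not None:
        g.attrs["config"] = json.dumps(config, default=str)


def read_meta(path: str | Path) -> dict[str, Any]:
    with h5py.File(path, "r") as f:
        raw = f.attrs.get("config")
        return json.loads(raw) if raw else {}


def save_potts(path, params: PottsParameters, config: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("h", data=params.h)
        f.create_dataset("J", data=params.J)
        f.attrs["kind"] = "potts"
        _write_meta(f, config)


def load_potts(path) -> PottsParameters:
    with h5py.File(path, "r") as f:
        return PottsParameters(f["h"][...], f["J"][...])


def save_couplings(path, cm: CouplingMatrix, config: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("Jmat", data=cm.Jmat)
        f.attrs["scale"] = cm.scale
        f.attrs["kind"] = "couplings"
        if cm.seq_a:
            f.attrs["seq_a"] = cm.seq_a
        if cm.seq_b:
            f.attrs["seq_b"] = cm.seq_b
        _write_meta(f, config)


def load_couplings(path) -> CouplingMatrix:
    with h5py.File(path, "r") as f:
        return CouplingMatrix(
            f["Jmat"][...],
            scale=float(f.attrs.get("scale", 1.0)),
            seq_a=f.attrs.get("seq_a"),
            seq_b=f.attrs.get("seq_b"),
        )


def save_system(path, system: CGSystem, config: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "system"
        f.attrs["box_shape"] = system.box.shape
        f.attrs["box_size"] = system.box.size
        f.attrs["temperature"] = system.temperature
        for i, chain in enumerate(system.chains):
            g = f.create_group(f"chain_{i}")
            g.attrs["sequence"] = chain.sequence
            g.create_dataset("coords", data=chain.coords)
        _write_meta(f, config)


def load_system(path) -> CGSystem:
    with h5py.File(path, "r") as f:
        chains = []
        i = 0
        while f"chain_{i}" in f:
            g = f[f"chain_{i}"]
            chains.append(CGChain(g.attrs["sequence"], g["coords"][...]))
            i += 1
        box = BoxSpec(f.attrs["box_shape"], float(f.attrs["box_size"]))
        return CGSystem(chains, box, float(f.attrs["temperature"]))


def save_trajectory(path, traj: Trajectory, config: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "trajectory"
        f.attrs["temperature"] = traj.temperature
        f.attrs["k_trans"] = traj.k_trans
        f.attrs["acceptance"] = traj.acceptance
        f.create_dataset("steps", data=np.asarray(traj.steps))
        f.create_dataset("energies", data=traj.energy_array())
        if traj.trans_raw:
            f.create_dataset("trans_raw", data=traj.trans_raw_array())
        for si, snap in enumerate(traj.states):
            g = f.create_group(f"snapshot_{si}")
            for ci, coords in enumerate(snap):
                g.create_dataset(f"chain_{ci}", data=np.asarray(coords))
        _write_meta(f, config)


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        traj = Trajectory(
            temperature=float(f.attrs["temperature"]),
            k_trans=float(f.attrs.get("k_trans", 1.0)),
            acceptance=float(f.attrs.get("acceptance", 0.0)),
        )
        traj.steps = [int(s) for s in f["steps"][...]]
        traj.energies = [float(e) for e in f["energies"][...]]
        if "trans_raw" in f:
            traj.trans_raw = [float(e) for e in f["trans_raw"][...]]
        for si in range(len(traj.steps)):
            g = f[f"snapshot_{si}"]
            snap = []
            ci = 0
            while f"chain_{ci}" in g:
                snap.append(g[f"chain_{ci}"][...])
                ci += 1
            traj.states.append(snap)
        return traj
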