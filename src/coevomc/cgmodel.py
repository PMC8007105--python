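"""Four-bead-per-residue coarse-grained protein model.

Each residue is reduced to its backbone N, CA, C atoms plus one side-chain
bead (SC) at the side chain's center of mass (glycine: SC coincides with
CA). Bond lengths and bond angles are recorded when a chain is built and are
held fixed thereafter: all conformational freedom lives in the backbone
dihedrals and in rigid-body placement, and every sampling move preserves the
recorded internal geometry exactly.

Coordinates are stored in Å. Box sizes are given in nm because the box
volume (in nm³) is what enters the dissociation-constant relation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import _geometry as geom
from .alphabet import THREE_TO_ONE

N, CA, C, SC = 0, 1, 2, 3
BEAD_NAMES = ("N", "CA", "C", "SC")

_ATOM_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "SE": 78.971}
_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


class BuildError(ValueError):
    """Raised when a structure cannot be mapped to the CG representation."""


@dataclasses.dataclass
class CGChain:
    """One protein chain in the 4-bead representation.

    Parameters
    ----------
    sequence
        One-letter residue codes, length n.
    coords
        Array of shape (n, 4, 3) in Å, beads ordered N, CA, C, SC.
    """

    sequence: str
    coords: np.ndarray
    reference_geometry: dict[str, np.ndarray] = dataclasses.field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.sequence)
        if self.coords.shape != (n, 4, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} != ({n}, 4, 3)"
            )
        if self.reference_geometry is None:
            self.reference_geometry = internal_geometry(self.coords)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def sc_coords(self) -> np.ndarray:
        return self.coords[:, SC, :]

    @property
    def ca_coords(self) -> np.ndarray:
        return self.coords[:, CA, :]

    def flat_coords(self) -> np.ndarray:
        """All beads as a (4n, 3) array, residue-major."""
        return self.coords.reshape(-1, 3)

    def copy(self) -> "CGChain":
        return CGChain(self.sequence, self.coords.copy(), self.reference_geometry)


@dataclasses.dataclass(frozen=True)
class BoxSpec:
    """Hard-walled confinement volume, cubic or spherical, centered at 0.

    ``size`` is the cube edge or the sphere radius, in nm.
    """

    shape: str = "cube"
    size: float = 10.0

    def __post_init__(self) -> None:
        if self.shape not in ("cube", "sphere"):
            raise ValueError(f"unknown box shape {self.shape!r}")
        if self.size <= 0:
            raise ValueError("box size must be positive")

    @property
    def volume_nm3(self) -> float:
        if self.shape == "cube":
            return self.size**3
        return 4.0 / 3.0 * np.pi * self.size**3

    @property
    def size_angstrom(self) -> float:
        return self.size * 10.0

    def contains(self, coords: np.ndarray) -> bool:
        """True iff every point (Å) lies inside the walls."""
        coords = np.atleast_2d(coords)
        if self.shape == "cube":
            half = self.size_angstrom / 2.0
            return bool(np.all(np.abs(coords) <= half))
        return bool(np.all(np.sum(coords**2, axis=1) <= self.size_angstrom**2))

    @classmethod
    def cube_from_volume(cls, volume_nm3: float) -> "BoxSpec":
        return cls("cube", volume_nm3 ** (1.0 / 3.0))

    @classmethod
    def sphere_from_volume(cls, volume_nm3: float) -> "BoxSpec":
        return cls("sphere", (volume_nm3 * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


@dataclasses.dataclass
class CGSystem:
    """One or more CG chains in a box at temperature T (energy units, k_B=1)."""

    chains: list[CGChain]
    box: BoxSpec = dataclasses.field(default_factory=BoxSpec)
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("a CGSystem needs at least one chain")

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def all_coords(self) -> np.ndarray:
        return np.concatenate([c.flat_coords() for c in self.chains])

    def copy(self) -> "CGSystem":
        return CGSystem([c.copy() for c in self.chains], self.box, self.temperature)


# ---------------------------------------------------------------------------
# internal geometry bookkeeping

def internal_geometry(coords: np.ndarray) -> dict[str, np.ndarray]:
    """Bond lengths (Å) and bond angles (rad) fixed by the model.

    Covers N-CA, CA-C, CA-SC and peptide C-N bonds, plus every bond angle
    whose vertex sits on the backbone, including the two side-chain
    attachment angles.
    """
    c = coords
    out: dict[str, np.ndarray] = {}
    out["bond_N_CA"] = np.linalg.norm(c[:, CA] - c[:, N], axis=1)
    out["bond_CA_C"] = np.linalg.norm(c[:, C] - c[:, CA], axis=1)
    out["bond_CA_SC"] = np.linalg.norm(c[:, SC] - c[:, CA], axis=1)
    out["bond_C_N"] = np.linalg.norm(c[1:, N] - c[:-1, C], axis=1)

    def angles(a, b, d):
        return np.array([geom.angle_between(x, y, z) for x, y, z in zip(a, b, d)])

    out["angle_N_CA_C"] = angles(c[:, N], c[:, CA], c[:, C])
    out["angle_N_CA_SC"] = angles(c[:, N], c[:, CA], c[:, SC])
    out["angle_C_CA_SC"] = angles(c[:, C], c[:, CA], c[:, SC])
    if len(c) > 1:
        out["angle_CA_C_N"] = angles(c[:-1, CA], c[:-1, C], c[1:, N])
        out["angle_C_N_CA"] = angles(c[:-1, C], c[1:, N], c[1:, CA])
    else:
        out["angle_CA_C_N"] = np.zeros(0)
        out["angle_C_N_CA"] = np.zeros(0)
    return out


@dataclasses.dataclass(frozen=True)
class GeometryViolation:
    kind: str
    index: int
    deviation: float


def validate_geometry(chain: CGChain, tol: float = 1e-6) -> list[GeometryViolation]:
    """List every bond length/angle deviating from construction values.

    An empty report certifies the rigid-geometry contract.
    """
    current = internal_geometry(chain.coords)
    report: list[GeometryViolation] = []
    for key, ref in chain.reference_geometry.items():
        dev = np.abs(current[key] - ref)
        for idx in np.nonzero(dev > tol)[0]:
            report.append(GeometryViolation(key, int(idx), float(dev[idx])))
    return report


def backbone_dihedrals(chain: CGChain) -> np.ndarray:
    """(φ, ψ) per residue in degrees, NaN where undefined (termini).

    φ_i = C(i-1)-N(i)-CA(i)-C(i); ψ_i = N(i)-CA(i)-C(i)-N(i+1), with the
    standard sign convention.
    """
    if chain.n_residues < 2:
        raise ValueError("dihedrals need a chain of length >= 2")
    c = chain.coords
    n = chain.n_residues
    out = np.full((n, 2), np.nan)
    for i in range(n):
        if i > 0:
            out[i, 0] = np.degrees(
                geom.dihedral(c[i - 1, C], c[i, N], c[i, CA], c[i, C])
            )
        if i < n - 1:
            out[i, 1] = np.degrees(
                geom.dihedral(c[i, N], c[i, CA], c[i, C], c[i + 1, N])
            )
    return out


# ---------------------------------------------------------------------------
# dihedral rotations (the move primitives; geometry-exact by construction)

def dihedral_atom_sets(n_res: int, i: int, which: str) -> tuple[np.ndarray, np.ndarray]:
    """Flat bead indices (residue-major, 4 beads each) moved by rotating
    dihedral ``which`` of residue i: (downstream set, upstream set).

    Either set may be rotated (about the same axis, with opposite angle
    sign conventions handled by the caller); both choices change the
    torsion while preserving every bond length and angle.
    """
    def flat(res: int, bead: int) -> int:
        return 4 * res + bead

    if which == "phi":
        if i == 0:
            raise ValueError("phi undefined for the first residue")
        down = [flat(i, C), flat(i, SC)]
        down += [flat(r, b) for r in range(i + 1, n_res) for b in range(4)]
        up = [flat(r, b) for r in range(i) for b in range(4)]
    elif which == "psi":
        if i == n_res - 1:
            raise ValueError("psi undefined for the last residue")
        down = [flat(r, b) for r in range(i + 1, n_res) for b in range(4)]
        up = [flat(i, N), flat(i, SC)]
        up += [flat(r, b) for r in range(i) for b in range(4)]
    else:
        raise ValueError(f"dihedral must be 'phi' or 'psi', got {which!r}")
    return np.array(down, dtype=int), np.array(up, dtype=int)


def rotate_dihedral(
    coords: np.ndarray, i: int, which: str, angle_rad: float,
    segment: str = "smaller",
) -> np.ndarray:
    """Return new (n,4,3) coordinates with one backbone torsion rotated.

    ``segment`` selects which rigid piece moves: "downstream", "upstream"
    or "smaller" (the side with fewer beads; ties go downstream). Rotating
    the upstream piece uses the opposite angle so that the torsion change
    equals ``angle_rad`` in both cases.
    """
    n_res = coords.shape[0]
    down, up = dihedral_atom_sets(n_res, i, which)
    if which == "phi":
        origin, axis_end = coords[i, N], coords[i, CA]
    else:
        origin, axis_end = coords[i, CA], coords[i, C]
    if segment == "smaller":
        segment = "downstream" if len(down) <= len(up) else "upstream"
    if segment == "downstream":
        moved, sign = down, 1.0
    elif segment == "upstream":
        moved, sign = up, -1.0
    else:
        raise ValueError(f"unknown segment {segment!r}")
    flat = coords.reshape(-1, 3).copy()
    flat[moved] = geom.rotate_about_bond(
        flat[moved], origin, axis_end, sign * angle_rad
    )
    return flat.reshape(coords.shape)


# ---------------------------------------------------------------------------
# PDB input / output

def build_from_pdb(path: str | Path, chain_ids: Sequence[str] | None = None) -> list[CGChain]:
    """Map a PDB file onto CG chains.

    The SC bead goes at the mass-weighted centroid of the residue's
    side-chain heavy atoms (everything but N, CA, C, O/OXT and hydrogens);
    glycine's SC bead coincides with CA. Disordered atoms resolve to the
    highest-occupancy altloc (Biopython's default selection).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    model = parser.get_structure("s", str(path))[0]
    chains: list[CGChain] = []
    for chain in model:
        if chain_ids is not None and chain.id not in chain_ids:
            continue
        seq: list[str] = []
        coords: list[np.ndarray] = []
        for res in chain:
            if res.id[0] != " ":
                continue  # skip waters / hetero residues
            resname = res.get_resname()
            if resname not in THREE_TO_ONE:
                raise BuildError(f"nonstandard residue {resname} {res.id[1]}")
            for atom_name in ("N", "CA", "C"):
                if atom_name not in res:
                    raise BuildError(
                        f"missing backbone atom {atom_name} in "
                        f"{resname} {res.id[1]} chain {chain.id}"
                    )
            letter = THREE_TO_ONE[resname]
            sc_atoms = [
                a for a in res.get_atoms()
                if a.get_name() not in _BACKBONE_ATOMS and a.element != "H"
            ]
            if sc_atoms:
                masses = np.array(
                    [_ATOM_MASS.get(a.element, 12.011) for a in sc_atoms]
                )
                pos = np.stack([a.get_coord() for a in sc_atoms]).astype(float)
                sc = (masses[:, None] * pos).sum(axis=0) / masses.sum()
            else:
                sc = np.asarray(res["CA"].get_coord(), dtype=float)
            seq.append(letter)
            coords.append(np.stack([
                res["N"].get_coord(), res["CA"].get_coord(),
                res["C"].get_coord(), sc,
            ]).astype(float))
        if seq:
            chains.append(CGChain("".join(seq), np.stack(coords)))
    if chain_ids is not None and len(chains) != len(chain_ids):
        raise BuildError(f"not all requested chains {chain_ids} found")
    if not chains:
        raise BuildError("no protein chains found")
    return chains


_ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def write_pdb(chains: Iterable[CGChain], path: str | Path) -> None:
    """Write CG chains as PDB ATOM records (SC as a pseudo-atom named SC)."""
    chain_letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    serial = 1
    with open(path, "w") as fh:
        for ci, chain in enumerate(chains):
            cid = chain_letters[ci % len(chain_letters)]
            for ri, aa in enumerate(chain.sequence):
                res3 = _ONE_TO_THREE[aa]
                for bead, name in enumerate(BEAD_NAMES):
                    x, y, z = chain.coords[ri, bead]
                    element = "C" if name in ("C", "SC") else "N"
                    fh.write(
                        f"ATOM  {serial:5d} {name:<4s} {res3} {cid}{ri + 1:4d}"
                        f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {element:>2s}\n"
                    )
                    serial += 1
            fh.write("TER\n")
        fh.write("END\n")


def read_cg_pdb(path: str | Path) -> list[CGChain]:
    """Read chains written by :func:`write_pdb` (N/CA/C/SC records)."""
    chains: dict[str, dict[int, dict[str, np.ndarray]]] = {}
    resnames: dict[str, dict[int, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("ATOM"):
                continue
            name = line[12:16].strip()
            res3 = line[17:20]
            cid = line[21]
            resi = int(line[22:26])
            xyz = np.array([line[30:38], line[38:46], line[46:54]], dtype=float)
            if cid not in chains:
                chains[cid] = {}
                resnames[cid] = {}
                order.append(cid)
            chains[cid].setdefault(resi, {})[name] = xyz
            resnames[cid][resi] = res3
    out = []
    for cid in order:
        residues = sorted(chains[cid])
        seq = "".join(THREE_TO_ONE[resnames[cid][r]] for r in residues)
        coords = np.stack([
            np.stack([chains[cid][r][n] for n in BEAD_NAMES]) for r in residues
        ])
        out.append(CGChain(seq, coords))
    return out


# ---------------------------------------------------------------------------
# initial placement

def place_chains_randomly(
    chains: Sequence[CGChain],
    box: BoxSpec,
    rng: np.random.Generator,
    min_separation: float = 4.0,
    max_tries: int = 1000,
) -> list[CGChain]:
    """Rigidly place chains at random positions/orientations in the box.

    Chains are placed one at a time; a placement is retried until all
    beads are inside the walls and no inter-chain bead pair comes closer
    than ``min_separation`` (Å).
    """
    from scipy.spatial.transform import Rotation

    placed: list[CGChain] = []
    placed_beads: list[np.ndarray] = []
    half = box.size_angstrom / 2.0
    for chain in chains:
        centered = chain.flat_coords() - chain.flat_coords().mean(axis=0)
        for _ in range(max_tries):
            R = Rotation.random(random_state=rng).as_matrix()
            shift = rng.uniform(-half, half, size=3)
            trial = centered @ R.T + shift
            if not box.contains(trial):
                continue
            if placed_beads:
                other = np.concatenate(placed_beads)
                d2 = np.sum(
                    (trial[:, None, :] - other[None, :, :]) ** 2, axis=-1
                )
                if d2.min() < min_separation**2:
                    continue
            new = chain.copy()
            new.coords = trial.reshape(chain.coords.shape)
            placed.append(new)
            placed_beads.append(trial)
            break
        else:
            raise BuildError(
                f"could not place chain of {chain.n_residues} residues in the "
                f"box after {max_tries} tries"
            )
    return placed
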