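"""Low-level 3-D geometry: dihedrals, axis rotations, internal-coordinate
placement. Angles at this layer are radians unless a name says degrees."""

from __future__ import annotations

import numpy as np


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle (radians, IUPAC convention) of four points.

    Returns NaN when either bonded triple is collinear (undefined torsion).
    """
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    b1n = np.linalg.norm(b1)
    if n1n < 1e-10 or n2n < 1e-10 or b1n < 1e-10:
        return float("nan")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1 / b1n))
    return float(np.arctan2(y, x))


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("rotation axis has zero length")
    k = axis / n
    K = np.array([
        [0.0, -k[2], k[1]],
        [k[2], 0.0, -k[0]],
        [-k[1], k[0], 0.0],
    ])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def rotate_about_bond(
    coords: np.ndarray, origin: np.ndarray, axis_end: np.ndarray, angle: float
) -> np.ndarray:
    """Rotate points about the line origin->axis_end by ``angle``."""
    R = rotation_about_axis(axis_end - origin, angle)
    return (coords - origin) @ R.T + origin


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle: float, torsion: float,
) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d.

    d is placed at distance ``bond`` from c, with angle b-c-d = ``angle``
    and dihedral a-b-c-d = ``torsion``.
    """
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    M = np.stack([bc, m, n], axis=1)
    return c + M @ d_local


def angle_between(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Bond angle a-b-c in radians."""
    u = a - b
    v = c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-10 or nv < 1e-10:
        return 0.0  # degenerate (e.g. glycine SC on CA): treat as fixed
    cosang = np.dot(u, v) / (nu * nv)
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def wrap_angle_deg(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap an angle difference in degrees to (-180, 180]."""
    return -((-np.asarray(x) + 180.0) % 360.0 - 180.0)


def kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Minimal RMSD between two point sets after optimal superposition."""
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    C = x.T @ y
    U, S, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(U @ Vt))
    S = S.copy()
    S[-1] *= d
    # E = sum|x|^2 + sum|y|^2 - 2*trace(optimal)
    msd = (np.sum(x * x) + np.sum(y * y) - 2.0 * np.sum(S)) / len(x)
    return float(np.sqrt(max(msd, 0.0)))
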