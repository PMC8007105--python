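"""Amino-acid alphabet shared across the package.

The 20 standard residues are ordered alphabetically by one-letter code; the
gap character ``-`` is appended as state 20, giving the q = 21 alphabet used
when fitting the family model. Ambiguous or unknown codes (X, B, Z, J, O, U,
and the Stockholm ``.``) are coerced to the gap state.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
ALPHABET: str = AMINO_ACIDS + GAP
GAP_STATE: int = len(AMINO_ACIDS)
Q: int = len(ALPHABET)

_TO_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_COERCE_TO_GAP = set("XBZJOU.*")

# Three-letter PDB residue names -> one-letter codes (standard 20 only).
THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}


def char_to_state(c: str) -> int:
    """Map one residue character to its integer state (gap for unknowns)."""
    c = c.upper()
    if c in _TO_INDEX:
        return _TO_INDEX[c]
    if c in _COERCE_TO_GAP or c == GAP:
        return GAP_STATE
    raise ValueError(f"unrecognized residue character {c!r}")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string as an int8 state vector."""
    return np.array([char_to_state(c) for c in seq], dtype=np.int8)


def decode(states: np.ndarray) -> str:
    """Inverse of :func:`encode` (unknowns were already coerced to gap)."""
    return "".join(ALPHABET[int(s)] for s in states)


def aa_index(c: str) -> int:
    """Index of a residue in the 20-letter (gap-free) alphabet."""
    c = c.upper()
    i = _TO_INDEX.get(c)
    if i is None or i == GAP_STATE:
        raise ValueError(f"{c!r} is not one of the 20 standard residues")
    return i
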