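"""Family alignments: parsing, projection onto a reference, redundancy filtering.

A family alignment (e.g. a Pfam full alignment) is read into an :class:`MSA`,
projected onto the sequence of a target structure by dropping every column
where the reference carries a gap, and deduplicated by a greedy 90%-identity
filter. The resulting integer-encoded alignment is what the coupling
inference consumes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO

from . import alphabet


class AlignmentFormatError(ValueError):
    """Raised for ragged or otherwise malformed alignments."""


@dataclasses.dataclass
class MSA:
    """A multiple sequence alignment over the 21-state alphabet.

    Parameters
    ----------
    sequences
        Equal-length uppercase strings over the 20 amino acids plus gap.
    ids
        One identifier per sequence.
    """

    sequences: list[str]
    ids: list[str]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.ids):
            raise ValueError("sequences and ids must have equal length")
        if not self.sequences:
            raise AlignmentFormatError("alignment contains no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            bad = next(
                i for s, i in zip(self.sequences, self.ids)
                if len(s) != len(self.sequences[0])
            )
            raise AlignmentFormatError(f"ragged alignment: record {bad!r}")
        self.sequences = [_canonicalize(s) for s in self.sequences]

    @property
    def n_seq(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def q(self) -> int:
        return alphabet.Q

    def encoded(self) -> np.ndarray:
        """Integer matrix of shape (n_seq, L) with values in [0, q)."""
        return np.stack([alphabet.encode(s) for s in self.sequences])

    @classmethod
    def from_encoded(cls, mat: np.ndarray, ids: Sequence[str] | None = None) -> "MSA":
        seqs = [alphabet.decode(row) for row in np.asarray(mat)]
        if ids is None:
            ids = [f"seq{i}" for i in range(len(seqs))]
        return cls(seqs, list(ids))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, MSA)
            and self.sequences == other.sequences
            and self.ids == other.ids
        )


@dataclasses.dataclass(frozen=True)
class ProjectionMap:
    """Bookkeeping for projecting an alignment onto a gapless reference.

    ``kept_columns[i]`` is the alignment column behind reference position
    ``i``; ``ref_sequence`` is the reference with its gaps removed.
    """

    kept_columns: tuple[int, ...]
    ref_sequence: str

    def __post_init__(self) -> None:
        if len(self.kept_columns) != len(self.ref_sequence):
            raise ValueError("kept_columns and ref_sequence length mismatch")
        if len(set(self.kept_columns)) != len(self.kept_columns):
            raise ValueError("kept_columns must be injective")

    def ref_to_column(self, i: int) -> int:
        return self.kept_columns[i]

    def reinsert_gaps(self, projected_row: str, total_columns: int) -> str:
        """Place a projected row back into full alignment coordinates."""
        out = [alphabet.GAP] * total_columns
        for c, ch in zip(self.kept_columns, projected_row):
            out[c] = ch
        return "".join(out)


def _canonicalize(seq: str) -> str:
    """Uppercase and coerce unknown characters to the gap symbol."""
    return "".join(
        alphabet.ALPHABET[alphabet.char_to_state(c)] for c in seq.upper()
    )


def read_alignment(path: str | Path, format: str = "fasta") -> MSA:
    """Read a Stockholm or aligned-FASTA file into an :class:`MSA`.

    Unknown residue codes (X, B, Z, ...) and the Stockholm ``.`` are mapped
    to the gap state.
    """
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {format!r}")
    path = Path(path)
    try:
        aln = AlignIO.read(str(path), format)
    except FileNotFoundError:
        raise
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    return MSA([str(rec.seq) for rec in aln], [rec.id for rec in aln])


def write_fasta(msa: MSA, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in zip(msa.ids, msa.sequences):
            fh.write(f">{rid}\n{seq}\n")


def project_to_reference(msa: MSA, ref_id_or_seq: str) -> tuple[MSA, ProjectionMap]:
    """Drop every column where the reference row carries a gap.

    The reference may be named by id or given as an (aligned or unaligned)
    sequence; an unaligned sequence is matched against each row's gapless
    residues.
    """
    ref_row = _find_reference_row(msa, ref_id_or_seq)
    kept = tuple(i for i, c in enumerate(ref_row) if c != alphabet.GAP)
    if not kept:
        raise LookupError("reference row is all gaps; nothing to project onto")
    projected = [
        "".join(seq[c] for c in kept) for seq in msa.sequences
    ]
    pmap = ProjectionMap(kept, "".join(ref_row[c] for c in kept))
    return MSA(projected, list(msa.ids)), pmap


def _find_reference_row(msa: MSA, ref: str) -> str:
    if ref in msa.ids:
        return msa.sequences[msa.ids.index(ref)]
    ref_canon = _canonicalize(ref)
    # exact aligned row
    for seq in msa.sequences:
        if seq == ref_canon:
            return seq
    # gapless match
    degapped = ref_canon.replace(alphabet.GAP, "")
    for seq in msa.sequences:
        if seq.replace(alphabet.GAP, "") == degapped:
            return seq
    raise LookupError(
        "reference not found: no id match and no row with the same "
        "non-gap residues in order"
    )


def fractional_identity(a: str, b: str) -> float:
    """Identity over all columns; gap==gap counts as a match."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned (equal length)")
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return matches / len(a)


def filter_redundant(
    msa: MSA,
    max_identity: float = 0.9,
    weights: Iterable[float] | None = None,
) -> MSA:
    """Greedy keep-first redundancy filter.

    Scanning in input order, a sequence is discarded if its fractional
    identity to any previously kept sequence exceeds ``max_identity``.
    The result is order-dependent by construction. ``weights`` is an
    optional per-sequence weight vector accepted for forward compatibility
    with soft reweighting schemes; it is carried through unused.
    """
    if not 0 < max_identity <= 1:
        raise ValueError("max_identity must be in (0, 1]")
    enc = msa.encoded()
    kept_idx: list[int] = []
    kept_rows: list[np.ndarray] = []
    L = msa.length
    for i in range(msa.n_seq):
        row = enc[i]
        redundant = any(
            float(np.count_nonzero(row == prev)) / L > max_identity
            for prev in kept_rows
        )
        if not redundant:
            kept_idx.append(i)
            kept_rows.append(row)
    return MSA(
        [msa.sequences[i] for i in kept_idx],
        [msa.ids[i] for i in kept_idx],
    )
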