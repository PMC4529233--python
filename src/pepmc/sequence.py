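"""Peptide sequences, the single-point mutation move, and small-space enumeration.

The optimizer evolves a fixed-length peptide over a residue alphabet (the 20
canonical amino acids by default).  The only move is a single-point
substitution: one position is redrawn uniformly, the replacement residue is
drawn uniformly from the alphabet *excluding* the incumbent.  This kernel is
symmetric (``P(p→q) = P(q→p)`` for every Hamming-1 pair), which is what the
Metropolis rule needs to target the Boltzmann measure, and it connects the
whole sequence space in at most ``length`` moves.

Exhaustive enumeration is provided for small oracle spaces where the exact
partition function is computable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: One-letter codes of the 20 canonical amino acids, alphabetically ordered.
CANONICAL_AA: str = "ACDEFGHIKLMNPQRSTVWY"

#: Default enumeration cap for :func:`enumerate_space`.
DEFAULT_ENUMERATION_CAP: int = 10**6


class InvalidResidueError(ValueError):
    """A residue outside the declared alphabet (reports 1-based position)."""

    def __init__(self, residue: str, position: int, alphabet: str):
        self.residue = residue
        self.position = position
        super().__init__(
            f"invalid residue {residue!r} at position {position} "
            f"(alphabet: {alphabet})"
        )


class EnumerationCapError(ValueError):
    """Requested sequence space exceeds the configured enumeration cap."""


def _canonical_alphabet(alphabet: Iterable[str]) -> str:
    letters = sorted({a.upper() for a in alphabet})
    for a in letters:
        if len(a) != 1 or not a.isalpha():
            raise ValueError(f"alphabet entries must be single letters, got {a!r}")
    if not letters:
        raise ValueError("alphabet must be non-empty")
    return "".join(letters)


@dataclass(frozen=True)
class Peptide:
    """A fixed-length peptide sequence over a declared alphabet.

    Parameters
    ----------
    sequence
        Upper-case one-letter residue string.
    alphabet
        Sorted string of allowed one-letter codes.
    pose_id
        Opaque conformation handle assigned by a scoring backend; ``None``
        before the peptide has ever been scored.
    """

    sequence: str
    alphabet: str = CANONICAL_AA
    pose_id: str | None = field(default=None, compare=False)

    def __len__(self) -> int:
        return len(self.sequence)

    def with_pose(self, pose_id: str) -> "Peptide":
        return Peptide(self.sequence, self.alphabet, pose_id)

    def replace_residue(self, position: int, residue: str) -> "Peptide":
        """Return a copy with the residue at 0-based ``position`` replaced."""
        seq = self.sequence
        return Peptide(seq[:position] + residue + seq[position + 1 :], self.alphabet)


def make_peptide(sequence_text: str, alphabet: Iterable[str] = CANONICAL_AA) -> Peptide:
    """Validate ``sequence_text`` against ``alphabet`` and build a :class:`Peptide`.

    Comparison is case-insensitive; the stored sequence is upper case.
    Raises :class:`InvalidResidueError` naming the first offending character
    and its 1-based position.
    """
    if not sequence_text:
        raise ValueError("sequence must be non-empty")
    canon = _canonical_alphabet(alphabet)
    seq = sequence_text.upper()
    allowed = set(canon)
    for i, residue in enumerate(seq, start=1):
        if residue not in allowed:
            raise InvalidResidueError(residue, i, canon)
    return Peptide(seq, canon)


def mutate(p: Peptide, rng: np.random.Generator) -> Peptide:
    """Single-point substitution move.

    The position is uniform over the chain; the replacement residue is uniform
    over the alphabet minus the incumbent, so the proposal never re-proposes
    the current sequence.  The input peptide is not modified.
    """
    if len(p.alphabet) < 2:
        raise ValueError("mutation requires an alphabet of size >= 2")
    position = int(rng.integers(len(p)))
    current = p.sequence[position]
    choices = [a for a in p.alphabet if a != current]
    residue = choices[int(rng.integers(len(choices)))]
    return p.replace_residue(position, residue)


def enumerate_space(
    length: int,
    alphabet: Iterable[str] = CANONICAL_AA,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> list[Peptide]:
    """All peptides of ``length`` over ``alphabet``, in lexicographic order.

    Intended for small oracle spaces (exact Boltzmann distributions, brute
    force optima).  Raises :class:`EnumerationCapError` when
    ``len(alphabet)**length`` exceeds ``cap``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    canon = _canonical_alphabet(alphabet)
    n = len(canon) ** length
    if n > cap:
        raise EnumerationCapError(
            f"{len(canon)}^{length} = {n} sequences exceeds the cap of {cap}"
        )
    return [
        Peptide("".join(letters), canon)
        for letters in itertools.product(canon, repeat=length)
    ]


# ---------------------------------------------------------------------------
# FASTA I/O


def write_fasta(
    path: str | Path,
    peptides: Sequence[Peptide],
    names: Sequence[str] | None = None,
    metadata: Sequence[dict] | None = None,
) -> None:
    """Write peptides as plain FASTA, one record per candidate.

    ``metadata`` dicts are rendered on the description line as ``key=value``
    pairs (campaign provenance: run index, score, temperature, ...).
    """
    records = []
    for i, p in enumerate(peptides):
        name = names[i] if names is not None else f"peptide_{i + 1}"
        desc = ""
        if metadata is not None:
            desc = " ".join(f"{k}={v}" for k, v in metadata[i].items())
        records.append(SeqRecord(Seq(p.sequence), id=name, description=desc))
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def read_fasta(
    path: str | Path, alphabet: Iterable[str] = CANONICAL_AA
) -> list[tuple[str, Peptide]]:
    """Read a peptide FASTA, validating every record against ``alphabet``.

    Returns ``(name, Peptide)`` pairs in file order.
    """
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        out.append((record.id, make_peptide(str(record.seq), alphabet)))
    return out


def iter_fasta_metadata(path: str | Path) -> Iterator[tuple[str, dict]]:
    """Yield ``(name, key=value metadata)`` parsed from FASTA description lines."""
    for record in SeqIO.parse(str(path), "fasta"):
        meta = {}
        for token in record.description.split()[1:]:
            if "=" in token:
                key, value = token.split("=", 1)
                meta[key] = value
        yield record.id, meta
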