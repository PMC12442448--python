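"""Protein sequence and MSA I/O.

Sequences are plain amino-acid strings over the 20 canonical letters plus
``X`` for unknown residues. Author (literature) residue numbering is carried
through a ``numbering_offset`` instead of renumbering, so downstream reports
can cite residues the way structural papers do (S156, C64, ...). Ambiguity
codes ``U``/``B``/``Z`` are rejected: the sequences this pipeline deals with
are canonical.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
GAP = "-"


class SeqIOError(ValueError):
    """Base class for sequence I/O failures."""


class EmptyInputError(SeqIOError):
    pass


class AlphabetError(SeqIOError):
    """A character outside the allowed amino-acid alphabet."""

    def __init__(self, record: str, position: int, char: str):
        self.record = record
        self.position = position
        self.char = char
        super().__init__(
            f"record {record!r}: illegal character {char!r} at position {position}"
        )


class MsaFormatError(SeqIOError):
    pass


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence with optional signal-peptide annotation.

    ``numbering_offset`` maps string index 1 to author residue number
    ``numbering_offset``; i.e. author number of string position ``p`` (1-based)
    is ``p + numbering_offset - 1``.
    """

    id: str
    residues: str
    signal_len: int = 0
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        for i, ch in enumerate(self.residues, start=1):
            if ch not in ALPHABET:
                raise AlphabetError(self.id, i, ch)
        if self.residues and not 0 <= self.signal_len < len(self.residues):
            raise ValueError(
                f"signal_len {self.signal_len} out of range for length {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def author_number(self, string_pos: int) -> int:
        """Author residue number for 1-based string position."""
        if not 1 <= string_pos <= len(self.residues):
            raise IndexError(f"position {string_pos} outside 1..{len(self.residues)}")
        return string_pos + self.numbering_offset - 1

    def string_position(self, author_pos: int) -> int:
        """1-based string position for an author residue number."""
        p = author_pos - self.numbering_offset + 1
        if not 1 <= p <= len(self.residues):
            raise IndexError(f"author position {author_pos} not covered by sequence")
        return p

    def residue_at(self, author_pos: int) -> str:
        return self.residues[self.string_position(author_pos) - 1]


def trim_signal(seq: ProteinSequence, n: int) -> ProteinSequence:
    """Remove ``n`` N-terminal residues (a signal peptide), preserving author numbering.

    The cleavage length is an input: signal-peptide prediction is upstream of
    this pipeline. The common convention for structure-model alignment is to
    drop the first 40 residues.
    """
    if n < 0:
        raise ValueError("trim length must be non-negative")
    if n >= len(seq.residues):
        raise ValueError(
            f"cannot trim {n} residues from a sequence of length {len(seq.residues)}"
        )
    if n == 0:
        return seq
    return replace(
        seq,
        residues=seq.residues[n:],
        signal_len=max(0, seq.signal_len - n),
        numbering_offset=seq.numbering_offset + n,
    )


@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment: rows of equal-length gapped strings."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise MsaFormatError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def column_count(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        for r, s in self.rows:
            if r == rid:
                return s
        raise KeyError(rid)

    def degapped(self) -> list[ProteinSequence]:
        return [
            ProteinSequence(id=rid, residues=s.replace(GAP, "")) for rid, s in self.rows
        ]

    def column(self, i: int) -> str:
        if not 0 <= i < self.column_count:
            raise IndexError(f"column {i} outside 0..{self.column_count - 1}")
        return "".join(s[i] for _, s in self.rows)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _parse_fasta(handle: Iterable[str]) -> Iterator[tuple[str, str]]:
    header: str | None = None
    chunks: list[str] = []
    for line in handle:
        line = line.rstrip("\n")
        if line.startswith(">"):
            if header is not None:
                yield header, "".join(chunks)
            header = line[1:].split()[0] if line[1:].split() else line[1:]
            chunks = []
        elif line.strip():
            if header is None:
                raise SeqIOError("sequence data before first FASTA header")
            chunks.append(line.strip())
    if header is not None:
        yield header, "".join(chunks)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a (possibly gzipped) FASTA file of protein sequences.

    Lowercase letters are uppercased and ``*`` terminators stripped; any other
    non-alphabet character raises :class:`AlphabetError` naming the record and
    1-based position.
    """
    records: list[ProteinSequence] = []
    with _open_text(path) as fh:
        for rid, raw in _parse_fasta(fh):
            cleaned = raw.upper().rstrip("*")
            records.append(ProteinSequence(id=rid, residues=cleaned))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def read_msa_fasta(path: str | Path) -> Msa:
    """Read an aligned FASTA file; rows of unequal length are a format error."""
    rows: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for rid, raw in _parse_fasta(fh):
            aligned = raw.upper()
            for i, ch in enumerate(aligned, start=1):
                if ch not in ALPHABET and ch != GAP:
                    raise AlphabetError(rid, i, ch)
            rows.append((rid, aligned))
    try:
        return Msa(rows=tuple(rows))
    except MsaFormatError as e:
        raise MsaFormatError(f"{path}: {e}") from e


def write_msa_fasta(msa: Msa, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, s in msa.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
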