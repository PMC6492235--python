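"""Protein multiple-alignment container and readers.

The alignment is the data term of the dating model: aligned amino-acid
sequences over the 20 IUPAC one-letter codes plus ``-`` (gap) and ``X``
(unknown).  Both symbols are treated as missing data downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import AlignIO, SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALPHABET = frozenset(AMINO_ACIDS + GAP + UNKNOWN)


class AlignmentError(ValueError):
    """Ragged rows, duplicate ids, or an empty alignment."""


class AlphabetError(ValueError):
    """A residue outside the 22-symbol amino-acid alphabet."""


@dataclass(frozen=True)
class ProteinAlignment:
    """An immutable, validated amino-acid alignment.

    Parameters
    ----------
    ids
        Unique sequence labels, in file order.
    rows
        Equal-length uppercase strings over the 22-symbol alphabet.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    n_sites: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if not self.rows:
            raise AlignmentError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")
        length = len(self.rows[0])
        if length < 1:
            raise AlignmentError("alignment has zero columns")
        rows = tuple(r.upper() for r in self.rows)
        for label, row in zip(self.ids, rows):
            if len(row) != length:
                raise AlignmentError(
                    f"row {label!r} has {len(row)} columns, expected {length}"
                )
            bad = set(row) - ALPHABET
            if bad:
                raise AlphabetError(
                    f"illegal symbol {sorted(bad)[0]!r} in row {label!r}"
                )
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "n_sites", length)

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.ids, self.rows))

    def row(self, label: str) -> str:
        try:
            return self.rows[self.ids.index(label)]
        except ValueError:
            raise KeyError(label) from None


def read_alignment(path: str | Path, format: str = "fasta") -> ProteinAlignment:
    """Read a FASTA or relaxed sequential PHYLIP alignment.

    Lowercase residues are normalised to upper case; validation errors
    surface as :class:`AlignmentError` / :class:`AlphabetError`.
    """
    path = Path(path)
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"no FASTA records in {path}")
        ids = tuple(r.id for r in records)
        rows = tuple(str(r.seq) for r in records)
    elif format == "phylip":
        aln = AlignIO.read(str(path), "phylip-relaxed")
        ids = tuple(r.id for r in aln)
        rows = tuple(str(r.seq) for r in aln)
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    return ProteinAlignment(ids=ids, rows=rows)


def write_alignment(aln: ProteinAlignment, path: str | Path) -> None:
    """Write the alignment as FASTA (the pipeline's interchange format)."""
    with open(path, "w") as fh:
        for label, row in aln:
            fh.write(f">{label}\n{row}\n")
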