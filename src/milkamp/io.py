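"""FASTA proteome-set I/O and tabular output helpers.

Proteome sets are named collections of protein records (e.g. the milk-whey
proteomes of individual breeds, or a cheese proteome). Sequences are uppercase
strings over the 20 standard residues; the ambiguity letters B, J, O, U, X, Z
are retained and flagged — downstream scans and cleavage rules skip windows or
bonds that touch them, they are never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUITY_RESIDUES = frozenset("BJOUXZ")
VALID_RESIDUES = STANDARD_RESIDUES | AMBIGUITY_RESIDUES


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (with a line number where known)."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein: opaque id, free-text description, residue sequence."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residue letters {sorted(bad)}"
            )

    @property
    def ambiguous_positions(self) -> tuple[int, ...]:
        """1-based positions of ambiguity letters (B, J, O, U, X, Z)."""
        return tuple(
            i + 1 for i, c in enumerate(self.sequence) if c in AMBIGUITY_RESIDUES
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteomeSet:
    """A named, ordered collection of protein records with unique ids."""

    name: str
    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(
                    f"proteome {self.name!r}: duplicate protein id {rec.id!r}"
                )
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def read_fasta(path: str | Path, name: str | None = None) -> ProteomeSet:
    """Read one FASTA file into a :class:`ProteomeSet`.

    The header token before the first whitespace becomes the record id (a
    Uniprot-style ``sp|ACC|NAME`` token is kept whole — ids are opaque labels
    here). Wrapped and unwrapped sequence lines are both accepted. Empty files
    and sequence data appearing before the first header are errors.
    """
    path = Path(path)
    with open(path) as fh:
        lineno = 0
        first = None
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = line
                break
        if first is None:
            raise FastaParseError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise FastaParseError(
                f"{path}: line {lineno}: sequence data before first FASTA header"
            )
    records = []
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        seq = str(seq_rec.seq).upper()
        records.append(
            ProteinRecord(id=seq_rec.id, description=seq_rec.description, sequence=seq)
        )
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    try:
        return ProteomeSet(name=name or path.stem, records=records)
    except ValueError as exc:
        raise FastaParseError(f"{path}: {exc}") from exc


def write_fasta(proteome: ProteomeSet, path: str | Path) -> None:
    """Write a proteome set as FASTA with unwrapped sequence lines."""
    with open(path, "w") as fh:
        for rec in proteome:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n{rec.sequence}\n")


def unique_sequences(
    sets: Iterable[ProteomeSet],
) -> dict[str, set[str]]:
    """Map every distinct sequence string to the proteome names containing it."""
    out: dict[str, set[str]] = {}
    for ps in sets:
        for rec in ps:
            out.setdefault(rec.sequence, set()).add(ps.name)
    return out


def write_table(
    rows: pd.DataFrame | Iterable[Mapping],
    path: str | Path,
    float_format: str = "%.4g",
) -> None:
    """Write tabular rows as TSV with a header; floats at 4 significant digits."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
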