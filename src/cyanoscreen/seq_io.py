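"""Strict FASTA / alignment / TSV I/O shared by every pipeline stage.

All sequences use the IUPAC nucleotide alphabet plus ``-`` as the only gap
character. Lower case and ``U`` are normalised on ingest; anything else is
an error located by line number. Coordinates everywhere in this package are
0-based, half-open.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

#: IUPAC nucleotide codes mapped to the set of plain bases each denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

GAP = "-"
ALPHABET = frozenset(IUPAC_SETS) | {GAP}

#: inverse lookup: frozenset of bases -> minimal IUPAC code
SETS_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "S": "S", "W": "W", "N": "N",
    "B": "V", "V": "B", "D": "H", "H": "D",
    GAP: GAP,
}


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC string (degenerate codes included)."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"illegal IUPAC character {exc.args[0]!r}") from None


class FastaError(ValueError):
    """Malformed FASTA input; carries the offending line number (1-based)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(message + where)


class AlignmentError(ValueError):
    pass


def _normalise(residues: str) -> str:
    return residues.upper().replace("U", "T")


@dataclass(frozen=True)
class SequenceRecord:
    """An identified IUPAC nucleotide sequence, possibly gapped."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be a non-empty token, got {self.id!r}")
        object.__setattr__(self, "residues", _normalise(self.residues))
        if not self.residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains illegal characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def reverse_complement(self, new_id: str | None = None) -> "SequenceRecord":
        return SequenceRecord(new_id or self.id, revcomp(self.residues), self.description)


@dataclass(frozen=True)
class Alignment:
    """An ordered set of equal-length gapped rows with no all-gap column."""

    records: tuple[SequenceRecord, ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        if len(self.records) < 2:
            raise AlignmentError("an alignment needs at least 2 records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            ragged = sorted({r.id for r in self.records})
            raise AlignmentError(f"ragged record lengths among ids {ragged}")
        ncol = lengths.pop()
        for j in range(ncol):
            if all(r.residues[j] == GAP for r in self.records):
                raise AlignmentError(f"column {j} consists solely of gaps")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate record ids in alignment")

    @property
    def columns(self) -> int:
        return len(self.records[0])

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, j: int) -> list[str]:
        return [r.residues[j] for r in self.records]


def as_alignment(records: Iterable[SequenceRecord]) -> Alignment:
    return Alignment(tuple(records))


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into validated records, in file order.

    Raises :class:`FastaError` naming the line for malformed headers, empty
    sequences, illegal characters and duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(at_line: int):
        nonlocal header, chunks
        if header is None:
            return
        parts = header.split(None, 1)
        if not parts:
            raise FastaError("empty FASTA header", header_line)
        rid = parts[0]
        desc = parts[1] if len(parts) > 1 else ""
        seq = "".join(chunks)
        if not seq:
            raise FastaError(f"record {rid!r} has no sequence", header_line)
        if rid in seen:
            raise FastaError(f"duplicate record id {rid!r}", header_line)
        try:
            rec = SequenceRecord(rid, seq, desc)
        except ValueError as exc:
            raise FastaError(str(exc), at_line) from None
        seen.add(rid)
        records.append(rec)
        header, chunks = None, []

    with open(path) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno - 1)
                header = line[1:].strip()
                header_line = lineno
                if not header:
                    raise FastaError("empty FASTA header", lineno)
            else:
                if header is None:
                    raise FastaError("sequence data before any '>' header", lineno)
                chunks.append(line)
        flush(lineno)
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, wrap: int = 70) -> None:
    """Write records as wrapped FASTA; byte-deterministic for fixed input."""
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    if wrap < 1:
        raise ValueError("wrap width must be positive")
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i : i + wrap] + "\n")


def read_alignment_fasta(path: str | Path) -> Alignment:
    return as_alignment(read_fasta(path))


def write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    """Write a TSV report with a header row."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        for row in rows:
            w.writerow(row)


def read_tsv(path: str | Path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        rows = list(r)
    if not rows:
        raise ValueError(f"empty TSV file {path}")
    return rows[0], rows[1:]
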