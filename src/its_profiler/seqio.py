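"""FASTA reading/writing with normalization and validation.

Parsing is delegated to Bio.SeqIO; this layer adds the error reporting and
normalization the rest of the package relies on (unique ids, non-empty
sequences, U->T, ambiguity codes collapsed to N).
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO

from .records import ItsRecord, MsaBlock, SequenceError, check_unique_ids


class FastaParseError(SequenceError):
    """Raised when a FASTA file is malformed."""


def read_fasta(path: str | os.PathLike, source: str = "direct") -> list[ItsRecord]:
    """Read a FASTA file into normalized :class:`ItsRecord` objects.

    Accepts both line-wrapped and single-line dialects.  Raises
    :class:`FastaParseError` naming the offending entry for empty sequences,
    duplicate ids, or a file that does not start with a header.
    """
    path = os.fspath(path)
    with open(path) as fh:
        first = fh.read(1)
        if first == "":
            raise FastaParseError(f"{path}: empty file")
        if first != ">":
            raise FastaParseError(f"{path}: does not start with a FASTA header")
    records: list[ItsRecord] = []
    for entry in SeqIO.parse(path, "fasta"):
        seq = str(entry.seq)
        if not seq:
            raise FastaParseError(f"{path}: entry {entry.id!r} has an empty sequence")
        try:
            records.append(ItsRecord(id=entry.id, sequence=seq, source=source))
        except SequenceError as exc:
            raise FastaParseError(f"{path}: {exc}") from exc
    check_unique_ids(records)
    return records


def write_fasta(records: Iterable[ItsRecord], path: str | os.PathLike, width: int = 60) -> None:
    """Write records as FASTA wrapped at `width` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_alignment_fasta(path: str | os.PathLike) -> MsaBlock:
    """Read an aligned FASTA (gap '-') into an :class:`MsaBlock`."""
    path = os.fspath(path)
    labels, rows = [], []
    for entry in SeqIO.parse(path, "fasta"):
        labels.append(entry.id)
        rows.append(str(entry.seq).upper().replace("U", "T"))
    if not labels:
        raise FastaParseError(f"{path}: no alignment rows")
    return MsaBlock(labels=labels, rows=rows)


def write_alignment_fasta(msa: MsaBlock, path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for lab, row in zip(msa.labels, msa.rows):
            fh.write(f">{lab}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")
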