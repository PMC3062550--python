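"""Core domain types: sequence records, region annotations, alignments."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

logger = logging.getLogger(__name__)

#: Allowed residues after normalization.
ALPHABET = frozenset("ACGTN")

#: IUPAC ambiguity codes collapsed to N (N itself included for completeness).
_AMBIGUOUS = set("RYSWKMBDHVN")

VALID_SOURCES = ("direct", "clone", "consensus", "read")


class SequenceError(ValueError):
    """Raised for malformed or non-normalizable sequence input."""


def normalize_sequence(seq: str, *, record_id: str = "?") -> str:
    """Upper-case, map U->T, collapse non-N ambiguity codes to N.

    Ambiguity codes other than N are mapped to N with a logged warning;
    N never counts as a match, a GC base, or a pairable base downstream.
    """
    if not seq:
        raise SequenceError(f"record {record_id!r}: empty sequence")
    s = seq.upper().replace("U", "T")
    out = []
    n_ambiguous = 0
    for ch in s:
        if ch in "ACGT":
            out.append(ch)
        elif ch in _AMBIGUOUS:
            if ch != "N":
                n_ambiguous += 1
            out.append("N")
        else:
            raise SequenceError(
                f"record {record_id!r}: invalid character {ch!r} in sequence"
            )
    if n_ambiguous:
        logger.warning(
            "record %r: %d ambiguity code(s) mapped to N", record_id, n_ambiguous
        )
    return "".join(out)


@dataclass(frozen=True)
class ItsRecord:
    """One ITS sequence with identity, provenance and accession metadata.

    Parameters
    ----------
    id : str
        Unique label within a dataset.
    sequence : str
        Upper-case DNA over {A, C, G, T, N}; normalized at construction.
    source : str
        One of ``direct``, ``clone``, ``consensus``, ``read``.
    accession_meta : dict
        Free-form key-value metadata (accession code, genome label, section).
    """

    id: str
    sequence: str
    source: str = "direct"
    accession_meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if self.source not in VALID_SOURCES:
            raise SequenceError(
                f"record {self.id!r}: source {self.source!r} not in {VALID_SOURCES}"
            )
        object.__setattr__(
            self, "sequence", normalize_sequence(self.sequence, record_id=self.id)
        )

    def __len__(self) -> int:
        return len(self.sequence)

    def subregion(self, start: int, end: int) -> str:
        """1-based inclusive slice of the sequence."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise IndexError(
                f"record {self.id!r}: interval ({start},{end}) outside "
                f"[1,{len(self.sequence)}]"
            )
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class RegionAnnotation:
    """1-based inclusive ITS1 / 5.8S / ITS2 intervals within a record."""

    its1: tuple[int, int]
    r58s: tuple[int, int]
    its2: tuple[int, int]

    def __post_init__(self) -> None:
        for name, (s, e) in self.items():
            if s < 1 or e < s:
                raise ValueError(f"{name} interval ({s},{e}) invalid")
        if not (
            self.its1[1] < self.r58s[0] <= self.r58s[1] < self.its2[0]
        ):
            raise ValueError(
                f"regions out of order: ITS1={self.its1}, 5.8S={self.r58s}, "
                f"ITS2={self.its2}"
            )

    def items(self) -> Iterator[tuple[str, tuple[int, int]]]:
        yield "ITS1", self.its1
        yield "5.8S", self.r58s
        yield "ITS2", self.its2

    def length(self, region: str) -> int:
        mapping = {"ITS1": self.its1, "5.8S": self.r58s, "ITS2": self.its2}
        if region == "total":
            return self.its2[1] - self.its1[0] + 1
        s, e = mapping[region]
        return e - s + 1

    def validate_for(self, record: ItsRecord) -> None:
        if self.its2[1] > len(record.sequence):
            raise ValueError(
                f"annotation end {self.its2[1]} beyond record {record.id!r} "
                f"length {len(record.sequence)}"
            )


@dataclass
class MsaBlock:
    """A multiple sequence alignment: ordered labels + equal-length gapped rows."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in alignment")
        if self.rows:
            width = len(self.rows[0])
            for lab, row in zip(self.labels, self.rows):
                if len(row) != width:
                    raise ValueError(
                        f"row {lab!r} has length {len(row)}, expected {width}"
                    )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]

    def ungapped(self, label: str) -> str:
        return self.row(label).replace("-", "")

    def column(self, j: int) -> str:
        """0-based column as a string, one char per row."""
        return "".join(r[j] for r in self.rows)


def check_unique_ids(records: list[ItsRecord]) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for rec in records:
        if rec.id in seen:
            dups.append(rec.id)
        seen.add(rec.id)
    if dups:
        raise SequenceError(f"duplicate record id(s): {', '.join(sorted(set(dups)))}")
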