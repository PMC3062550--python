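"""Read placement and per-position read-depth profiling along an ITS contig."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import align
from .records import ItsRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_MIN_IDENTITY = 90.0
DEFAULT_MIN_LENGTH = 50


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Placement:
    read_id: str
    start: int  # 1-based inclusive on the contig
    end: int
    identity: float  # percent over aligned columns
    strand: str  # "+" or "-"


@dataclass
class ReadDepthProfile:
    contig_id: str
    depth: np.ndarray  # per-position counts, int

    @property
    def mean_rd(self) -> float:
        return float(self.depth.mean())


def _best_local(read_seq: str, contig_seq: str):
    row_r, row_c, score, _, (c_start, c_end) = align.pairwise_local(
        read_seq, contig_seq
    )
    identity = 100.0 * align.aligned_identity(row_r, row_c)
    aligned_len = c_end - c_start
    return score, identity, c_start, c_end, aligned_len


def place_reads(
    reads: list[ItsRecord],
    contig: ItsRecord,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_len: int = DEFAULT_MIN_LENGTH,
) -> tuple[list[Placement], list[str]]:
    """Place each read at its best local-alignment window on either strand.

    Reads failing the identity or aligned-length thresholds are returned in
    the second element (unplaced read ids).  An empty read set is not an
    error.
    """
    if len(contig.sequence) < min_len:
        raise ValueError(
            f"contig {contig.id!r} shorter than min_len ({len(contig.sequence)} < {min_len})"
        )
    placements: list[Placement] = []
    unplaced: list[str] = []
    for read in reads:
        fwd = _best_local(read.sequence, contig.sequence)
        rev = _best_local(reverse_complement(read.sequence), contig.sequence)
        strand, best = ("+", fwd) if fwd[0] >= rev[0] else ("-", rev)
        _, identity, c_start, c_end, aligned_len = best
        if identity >= min_identity and aligned_len >= min_len:
            placements.append(
                Placement(
                    read_id=read.id,
                    start=c_start + 1,
                    end=c_end,
                    identity=identity,
                    strand=strand,
                )
            )
        else:
            unplaced.append(read.id)
    return placements, unplaced


def depth_profile(placements: list[Placement], contig_length: int,
                  contig_id: str = "contig") -> ReadDepthProfile:
    """Exact per-position coverage counts from placements."""
    delta = np.zeros(contig_length + 1, dtype=np.int64)
    for p in placements:
        if not (1 <= p.start <= p.end <= contig_length):
            raise ValueError(
                f"placement of {p.read_id!r} ({p.start},{p.end}) outside "
                f"[1,{contig_length}]"
            )
        delta[p.start - 1] += 1
        delta[p.end] -= 1
    depth = np.cumsum(delta[:-1])
    return ReadDepthProfile(contig_id=contig_id, depth=depth)
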