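"""Sub-region delimitation by global alignment to an annotated reference.

The record is globally aligned to an annotated reference (affine gaps);
each reference boundary column is mapped to the aligned record position.
Boundary columns falling in gaps resolve to the nearest non-gap record
position in the direction of the conserved 5.8S, which keeps the 5.8S
interval intact.  Alignment quality is the percent identity over the
reference's 5.8S columns; below a configurable floor the delimitation is
rejected as unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import align
from .records import ItsRecord, RegionAnnotation

DEFAULT_IDENTITY_FLOOR = 60.0  # percent identity over 5.8S columns
MIN_RECORD_LENGTH = 300


class DelimitationError(ValueError):
    def __init__(self, message: str, score: float | None = None):
        super().__init__(message)
        self.score = score


@dataclass(frozen=True)
class AnnotatedReference:
    record: ItsRecord
    annotation: RegionAnnotation

    def __post_init__(self) -> None:
        self.annotation.validate_for(self.record)


@dataclass(frozen=True)
class DelimitationResult:
    annotation: RegionAnnotation
    score: float  # percent identity over the reference 5.8S columns


def default_reference() -> AnnotatedReference:
    """Packaged synthetic annotated reference with known boundaries.

    Deterministically generated; serves the role an annotated rice ITS
    sequence would in a real analysis.
    """
    from . import synth

    return synth.default_reference()


def _position_maps(ref_row: str, rec_row: str) -> tuple[list[int], list[int]]:
    """Per alignment column: 1-based source positions (0 where gapped)."""
    ref_pos, rec_pos = [], []
    r = q = 0
    for a, b in zip(ref_row, rec_row):
        if a != "-":
            r += 1
        if b != "-":
            q += 1
        ref_pos.append(r if a != "-" else 0)
        rec_pos.append(q if b != "-" else 0)
    return ref_pos, rec_pos


def _map_boundary(
    ref_pos: list[int], rec_pos: list[int], target: int, direction: int
) -> int:
    """Record position aligned to reference position `target`; if that
    column is a gap in the record, walk `direction` (+1 toward 3', -1
    toward 5') to the nearest non-gap record position."""
    col = next(c for c, rp in enumerate(ref_pos) if rp == target)
    c = col
    while 0 <= c < len(rec_pos):
        if rec_pos[c] != 0:
            return rec_pos[c]
        c += direction
    # fell off the alignment: clamp to the sequence end on that side
    return 1 if direction < 0 else max(rec_pos)


def delimit(
    record: ItsRecord,
    ref: AnnotatedReference | None = None,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
) -> DelimitationResult:
    """Locate ITS1 / 5.8S / ITS2 boundaries in `record` via the reference."""
    if ref is None:
        ref = default_reference()
    if len(record.sequence) < MIN_RECORD_LENGTH:
        raise DelimitationError(
            f"record {record.id!r} too short to delimit "
            f"({len(record.sequence)} nt < {MIN_RECORD_LENGTH})"
        )
    ref_row, rec_row, _ = align.pairwise_global(ref.record.sequence, record.sequence)
    ref_pos, rec_pos = _position_maps(ref_row, rec_row)

    ann = ref.annotation
    # score: identity over alignment columns covering the reference 5.8S
    s58, e58 = ann.r58s
    cols = [c for c, rp in enumerate(ref_pos) if rp and s58 <= rp <= e58]
    matches = sum(1 for c in cols if ref_row[c] == rec_row[c] and ref_row[c] != "N")
    score = 100.0 * matches / len(cols)
    if score < identity_floor:
        raise DelimitationError(
            f"delimitation unreliable for {record.id!r}: 5.8S identity "
            f"{score:.1f}% below floor {identity_floor:.1f}%",
            score=score,
        )

    # gaps resolve toward the conserved 5.8S
    its1_start = _map_boundary(ref_pos, rec_pos, ann.its1[0], +1)
    r58s_start = _map_boundary(ref_pos, rec_pos, ann.r58s[0], +1)
    r58s_end = _map_boundary(ref_pos, rec_pos, ann.r58s[1], -1)
    its2_end = _map_boundary(ref_pos, rec_pos, ann.its2[1], -1)

    annotation = RegionAnnotation(
        its1=(its1_start, r58s_start - 1),
        r58s=(r58s_start, r58s_end),
        its2=(r58s_end + 1, its2_end),
    )
    annotation.validate_for(record)
    return DelimitationResult(annotation=annotation, score=score)
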