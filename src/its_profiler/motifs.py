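"""Conserved 5.8S motif scanning (M1/M2/M3) with position-level mismatch calls."""

from __future__ import annotations

from dataclasses import dataclass, field

from . import align


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    canonical: str

    def __len__(self) -> int:
        return len(self.canonical)


#: The three conserved angiosperm 5.8S motifs.
M1 = MotifDefinition("M1", "CGATGAAGAACGTAGC")
M2 = MotifDefinition("M2", "GAATTGCAGAATCC")
M3 = MotifDefinition("M3", "TTTGAACGCA")
CANONICAL_MOTIFS = (M1, M2, M3)

#: Above this many mismatches the gapped-alignment fallback is consulted.
DEFAULT_MISMATCH_CEILING = 4


@dataclass
class MotifReport:
    motif: str
    best_start: int  # 1-based offset within the 5.8S region
    mismatch_positions: list[int] = field(default_factory=list)  # 1-based in motif
    mismatch_bases: list[str] = field(default_factory=list)
    indel_flag: bool = False

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)


def _indel_probe(canonical: str, region: str) -> tuple[str, str]:
    """Gap-friendly local alignment used only for the indel fallback."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -1.5
    aligner.extend_gap_score = -0.5
    aln = next(iter(aligner.align(canonical, region)))
    return str(aln[0]), str(aln[1])


def _hamming(window: str, canonical: str) -> int:
    # N counts as a mismatch (conservative for pseudogene calling)
    return sum(1 for a, b in zip(window, canonical) if a != b or a == "N")


def scan_motif(
    r58s_seq: str,
    motif: MotifDefinition,
    mismatch_ceiling: int = DEFAULT_MISMATCH_CEILING,
) -> MotifReport:
    """Best ungapped placement of a canonical motif within the 5.8S region.

    The offset minimizing Hamming distance wins, ties broken left-most.
    When the best distance exceeds `mismatch_ceiling` and a gapped local
    alignment explains the region better with an indel, `indel_flag` is set.
    """
    m = len(motif)
    if len(r58s_seq) < m:
        raise ValueError(
            f"5.8S region ({len(r58s_seq)} nt) shorter than motif {motif.name} ({m} nt)"
        )
    best_start, best_dist = 0, m + 1
    for off in range(len(r58s_seq) - m + 1):
        d = _hamming(r58s_seq[off : off + m], motif.canonical)
        if d < best_dist:
            best_start, best_dist = off, d
            if d == 0:
                break
    window = r58s_seq[best_start : best_start + m]
    positions, bases = [], []
    for k, (obs, can) in enumerate(zip(window, motif.canonical), start=1):
        if obs != can or obs == "N":
            positions.append(k)
            bases.append(obs)

    indel_flag = False
    if best_dist > mismatch_ceiling:
        row_m, row_s = _indel_probe(motif.canonical, r58s_seq)
        has_gap = "-" in row_m or "-" in row_s
        matched = sum(1 for a, b in zip(row_m, row_s) if a == b and a != "-")
        # the gapped hit must account for more motif bases than the best
        # ungapped placement does
        if has_gap and matched > m - best_dist:
            indel_flag = True

    return MotifReport(
        motif=motif.name,
        best_start=best_start + 1,
        mismatch_positions=positions,
        mismatch_bases=bases,
        indel_flag=indel_flag,
    )


def scan_all(r58s_seq: str, mismatch_ceiling: int = DEFAULT_MISMATCH_CEILING) -> dict[str, MotifReport]:
    return {
        m.name: scan_motif(r58s_seq, m, mismatch_ceiling) for m in CANONICAL_MOTIFS
    }
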