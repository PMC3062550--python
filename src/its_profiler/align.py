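"""Pairwise and progressive multiple alignment.

Pairwise global/local alignment is delegated to Bio.Align.PairwiseAligner
(affine gaps).  The progressive multiple aligner stacks pairwise profile
merges over a UPGMA guide tree: profiles are column base-frequency matrices,
profile-profile alignment is a linear-gap Needleman-Wunsch on expected
column scores, vectorized row-by-row with numpy.
"""

from __future__ import annotations

import logging

import numpy as np
from Bio import Align
from scipy.cluster.hierarchy import linkage

from .records import ItsRecord, MsaBlock

logger = logging.getLogger(__name__)

# Affine scores: match +1, mismatch -1, gap open -4, extend -1.  Biopython's
# open_gap_score applies to the first gap residue, so a length-L gap costs
# open + (L-1)*extend; -5/-1 reproduces 4 + L.
MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -5.0
GAP_EXTEND = -1.0

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}

# Column-vs-column expected score: ACGT diagonal +1, mismatch -1,
# base-vs-gap -2, gap-vs-gap 0.  N contributes nothing (zero row).
_PROFILE_SCORE = np.full((5, 5), MISMATCH)
np.fill_diagonal(_PROFILE_SCORE, MATCH)
_PROFILE_SCORE[4, :] = -2.0
_PROFILE_SCORE[:, 4] = -2.0
_PROFILE_SCORE[4, 4] = 0.0

_PROFILE_GAP = -2.0  # linear per-column penalty for a new gap column


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_global(a: str, b: str) -> tuple[str, str, float]:
    """Globally align two sequences; returns (gapped_a, gapped_b, score)."""
    aln = next(iter(_global_aligner().align(a, b)))
    return str(aln[0]), str(aln[1]), float(aln.score)


def pairwise_local(a: str, b: str) -> tuple[str, str, float, tuple[int, int], tuple[int, int]]:
    """Locally align; returns gapped rows, score and 0-based half-open spans."""
    aln = next(iter(_local_aligner().align(a, b)))
    (a_start, a_end) = aln.aligned[0][0][0], aln.aligned[0][-1][1]
    (b_start, b_end) = aln.aligned[1][0][0], aln.aligned[1][-1][1]
    return str(aln[0]), str(aln[1]), float(aln.score), (a_start, a_end), (b_start, b_end)


def aligned_identity(row_a: str, row_b: str) -> float:
    """Fraction identical over compared columns (gap-gap and N excluded;
    gap-vs-base counts as a mismatch)."""
    matches = compared = 0
    for x, y in zip(row_a, row_b):
        if x == "-" and y == "-":
            continue
        if x == "N" or y == "N":
            continue
        compared += 1
        if x == y:
            matches += 1
    if compared == 0:
        raise ValueError("no compared columns")
    return matches / compared


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

def _profile_of(rows: list[str]) -> np.ndarray:
    """(L, 5) frequency matrix over A,C,G,T,-; N contributes nothing."""
    n = len(rows)
    length = len(rows[0])
    prof = np.zeros((length, 5))
    for row in rows:
        for j, ch in enumerate(row):
            idx = _BASE_INDEX.get(ch)
            if idx is not None:
                prof[j, idx] += 1.0
    return prof / n


def _profile_dp(prof_a: np.ndarray, prof_b: np.ndarray) -> np.ndarray:
    """Linear-gap NW score matrix between two column profiles."""
    la, lb = prof_a.shape[0], prof_b.shape[0]
    scores = prof_a @ _PROFILE_SCORE @ prof_b.T
    gp = _PROFILE_GAP
    H = np.empty((la + 1, lb + 1))
    H[0] = gp * np.arange(lb + 1)
    j_idx = np.arange(lb + 1)
    for i in range(1, la + 1):
        diag = H[i - 1, :-1] + scores[i - 1]
        up = H[i - 1, 1:] + gp
        cand = np.empty(lb + 1)
        cand[0] = i * gp
        np.maximum(diag, up, out=cand[1:])
        # left-chain closure: H[i,j] = max_{k<=j} cand[k] + gp*(j-k)
        H[i] = np.maximum.accumulate(cand - gp * j_idx) + gp * j_idx
    return H


def _merge_profiles(block_a: MsaBlock, block_b: MsaBlock) -> MsaBlock:
    prof_a = _profile_of(block_a.rows)
    prof_b = _profile_of(block_b.rows)
    H = _profile_dp(prof_a, prof_b)
    scores = prof_a @ _PROFILE_SCORE @ prof_b.T
    gp = _PROFILE_GAP
    i, j = prof_a.shape[0], prof_b.shape[0]
    ops: list[str] = []  # 'D' diag, 'U' up (col from a), 'L' left (col from b)
    eps = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0 and abs(H[i, j] - (H[i - 1, j - 1] + scores[i - 1, j - 1])) < eps:
            ops.append("D"); i -= 1; j -= 1
        elif i > 0 and abs(H[i, j] - (H[i - 1, j] + gp)) < eps:
            ops.append("U"); i -= 1
        else:
            ops.append("L"); j -= 1
    ops.reverse()

    na, nb = block_a.n_rows, block_b.n_rows
    cols_a = [iter(row) for row in block_a.rows]
    cols_b = [iter(row) for row in block_b.rows]
    out_a: list[list[str]] = [[] for _ in range(na)]
    out_b: list[list[str]] = [[] for _ in range(nb)]
    for op in ops:
        if op in ("D", "U"):
            for k, it in enumerate(cols_a):
                out_a[k].append(next(it))
        else:
            for buf in out_a:
                buf.append("-")
        if op in ("D", "L"):
            for k, it in enumerate(cols_b):
                out_b[k].append(next(it))
        else:
            for buf in out_b:
                buf.append("-")
    return MsaBlock(
        labels=block_a.labels + block_b.labels,
        rows=["".join(r) for r in out_a] + ["".join(r) for r in out_b],
    )


def pairwise_distance_matrix(records: list[ItsRecord]) -> np.ndarray:
    """All-pairs (1 - identity) from global pairwise alignments."""
    n = len(records)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ra, rb, _ = pairwise_global(records[i].sequence, records[j].sequence)
            d = 1.0 - aligned_identity(ra, rb)
            dist[i, j] = dist[j, i] = d
    return dist


def progressive_align(records: list[ItsRecord], min_pair_identity: float = 0.5) -> MsaBlock:
    """Progressive MSA: pairwise distances -> UPGMA guide tree -> profile merges.

    Rows are returned sorted by record id (canonical order), making the
    result independent of input order.  Pairs below `min_pair_identity`
    trigger a warning but the alignment is still returned.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to align")
    records = sorted(records, key=lambda r: r.id)
    dist = pairwise_distance_matrix(records)
    if np.any(dist > 1.0 - min_pair_identity):
        worst = float(dist.max())
        logger.warning(
            "alignment contains a pair with identity %.1f%% (< %.0f%%)",
            100 * (1 - worst), 100 * min_pair_identity,
        )
    n = len(records)
    if n == 2:
        merged = _merge_profiles(
            MsaBlock([records[0].id], [records[0].sequence]),
            MsaBlock([records[1].id], [records[1].sequence]),
        )
    else:
        condensed = dist[np.triu_indices(n, k=1)]
        Z = linkage(condensed, method="average")
        blocks: dict[int, MsaBlock] = {
            i: MsaBlock([rec.id], [rec.sequence]) for i, rec in enumerate(records)
        }
        for step, (a, b, _, _) in enumerate(Z):
            merged = _merge_profiles(blocks.pop(int(a)), blocks.pop(int(b)))
            blocks[n + step] = merged
        (merged,) = blocks.values()
    order = sorted(range(len(merged.labels)), key=lambda k: merged.labels[k])
    return MsaBlock(
        labels=[merged.labels[k] for k in order],
        rows=[merged.rows[k] for k in order],
    )


def align_to_msa(msa: MsaBlock, record: ItsRecord) -> MsaBlock:
    """Align a single record against an existing alignment (profile merge)."""
    return _merge_profiles(msa, MsaBlock([record.id], [record.sequence]))
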