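"""Secondary-structure screening.

ITS2 folding uses maximum-cardinality nested base pairing (Nussinov-style
dynamic programming: canonical pairs AT/GC/GT, minimum hairpin loop of 3,
deterministic traceback).  This is a documented stand-in for thermodynamic
folding — the downstream checks are topological (four-helix layout, TGGT in
helix III, pyrimidine-pyrimidine bulge in helix II), not energetic.

The 5.8S check tests satisfiability of the six fixed helix pairing
constraints B4-B8b: "F i j k" prescribes that positions i..i+k-1 pair with
j..j-k+1 (1-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_CANONICAL_PAIRS = frozenset(
    [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")]
)

MIN_HAIRPIN_LOOP = 3
MIN_HELIX_PAIRS = 3
#: pairs separated by at most this many unpaired bases per strand stay in one helix
HELIX_MERGE_TOLERANCE = 3


class FoldingError(ValueError):
    pass


class Region58SError(ValueError):
    """5.8S too short for the constraint check (itself pseudogene evidence)."""


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _CANONICAL_PAIRS


@dataclass
class Helix:
    """A run of (nearly) stacked pairs; pairs sorted by 5' position."""

    pairs: list[tuple[int, int]]

    @property
    def start5(self) -> int:
        return self.pairs[0][0]

    @property
    def end3(self) -> int:
        return self.pairs[0][1]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class FoldResult:
    pairs: set[tuple[int, int]]  # 1-based, i < j
    helices: list[Helix]
    score: int


@dataclass
class StructureReport:
    its2_n_helices: int = 0
    tggt_in_helix3: bool = False
    pyr_pyr_bulge_helix2: bool = False
    r58s_constraints: dict[str, bool] = field(default_factory=dict)
    r58s_error: str | None = None

    @property
    def overall_its2_ok(self) -> bool:
        return self.its2_n_helices == 4 and self.tggt_in_helix3

    @property
    def overall_58s_ok(self) -> bool:
        if self.r58s_error is not None or not self.r58s_constraints:
            return False
        return all(self.r58s_constraints.values())


def _pairing_table(seq: str) -> list[np.ndarray]:
    """For each j, sorted array of k < j - MIN_HAIRPIN_LOOP that can pair seq[j]."""
    n = len(seq)
    partners: list[list[int]] = [[] for _ in range(n)]
    for j in range(n):
        limit = j - MIN_HAIRPIN_LOOP
        for k in range(limit):
            if can_pair(seq[k], seq[j]):
                partners[j].append(k)
    return [np.asarray(p, dtype=np.intp) for p in partners]


def max_pairing(seq: str) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """DP table and deterministic traceback of a maximum nested pairing.

    The objective is lexicographic: maximize the number of pairs, then
    minimize the summed pair span — encoded as pair value BIG - (j - i)
    with BIG = n^2, which exceeds any achievable span total.  This makes
    local stacked hairpins the unique optimum for designed stem-loop
    layouts and keeps the traceback deterministic.  Returns (table, pairs)
    with 0-based pairs.
    """
    n = len(seq)
    big = np.int64(n * n)
    M = np.zeros((n, n), dtype=np.int64)
    partners = _pairing_table(seq)

    def m(i: int, j: int) -> int:
        return int(M[i, j]) if i <= j else 0

    for j in range(MIN_HAIRPIN_LOOP + 1, n):
        col = partners[j]
        for i in range(j - MIN_HAIRPIN_LOOP - 1, -1, -1):
            best = M[i, j - 1]
            ks = col[col >= i]
            if ks.size:
                left = np.where(ks > i, M[i, np.maximum(ks - 1, i)], 0)
                inner = M[np.minimum(ks + 1, j - 1), j - 1]
                inner = np.where(ks + 1 <= j - 1, inner, 0)
                cand = int((left + inner + big - (j - ks)).max())
                if cand > best:
                    best = cand
            M[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)] if n > 0 else []
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_HAIRPIN_LOOP:
            continue
        if M[i, j] == M[i, j - 1]:
            stack.append((i, j - 1))
            continue
        ks = partners[j]
        ks = ks[ks >= i]
        target = int(M[i, j])
        chosen = None
        for k in ks[::-1]:  # right-most compatible partner first
            k = int(k)
            if m(i, k - 1) + m(k + 1, j - 1) + int(big) - (j - k) == target:
                chosen = k
                break
        if chosen is None:  # cannot happen if DP is consistent
            raise AssertionError("traceback failed")
        pairs.append((chosen, j))
        stack.append((chosen + 1, j - 1))
        stack.append((i, chosen - 1))
    return M, sorted(pairs)


def group_helices(
    pairs: list[tuple[int, int]],
    merge_tolerance: int = HELIX_MERGE_TOLERANCE,
    min_pairs: int = MIN_HELIX_PAIRS,
) -> list[Helix]:
    """Group sorted 1-based pairs into helices, tolerating small bulges
    and internal loops (≤ merge_tolerance unpaired bases per strand)."""
    if not pairs:
        return []
    pairs = sorted(pairs)
    runs: list[list[tuple[int, int]]] = [[pairs[0]]]
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        same = (
            0 < i2 - i1 <= merge_tolerance + 1
            and 0 < j1 - j2 <= merge_tolerance + 1
        )
        if same:
            runs[-1].append((i2, j2))
        else:
            runs.append([(i2, j2)])
    return [Helix(run) for run in runs if len(run) >= min_pairs]


def fold_its2(its2_seq: str) -> FoldResult:
    """Fold an ITS2 region; refuses sequences with > 20 % N."""
    n = len(its2_seq)
    if n < 40:
        raise FoldingError(f"ITS2 too short to fold ({n} nt < 40)")
    if its2_seq.count("N") / n > 0.20:
        raise FoldingError("ITS2 has > 20% undetermined bases; refusing to fold")
    _, pairs0 = max_pairing(its2_seq)
    pairs = [(i + 1, j + 1) for i, j in pairs0]
    helices = group_helices(pairs)
    return FoldResult(pairs=set(pairs), helices=helices, score=len(pairs))


_PYRIMIDINES = frozenset("CT")


def check_its2_topology(fold: FoldResult, its2_seq: str) -> StructureReport:
    """Four-helix layout check: helices numbered I-IV in 5'->3' order of
    their 5' strands; TGGT must occur within the helix-III span (stem plus
    loop); helix II must carry an internal loop with exactly one unpaired
    pyrimidine on each strand."""
    report = StructureReport()
    helices = sorted(fold.helices, key=lambda h: h.start5)
    report.its2_n_helices = len(helices)
    if len(helices) >= 3:
        h3 = helices[2]
        span = its2_seq[h3.start5 - 1 : h3.end3]
        report.tggt_in_helix3 = "TGGT" in span
    if len(helices) >= 2:
        h2 = helices[1]
        for (i1, j1), (i2, j2) in zip(h2.pairs, h2.pairs[1:]):
            if i2 - i1 == 2 and j1 - j2 == 2:
                b5 = its2_seq[i1]      # unpaired base between i1 and i2 (0-based i1)
                b3 = its2_seq[j2]      # unpaired base between j2 and j1
                if b5 in _PYRIMIDINES and b3 in _PYRIMIDINES:
                    report.pyr_pyr_bulge_helix2 = True
                    break
    return report


@dataclass(frozen=True)
class HelixConstraint:
    name: str
    i: int  # start of 5' strand
    j: int  # end of 3' strand
    k: int  # run length; i..i+k-1 pairs j..j-k+1

    def prescribed_pairs(self) -> list[tuple[int, int]]:
        return [(self.i + t, self.j - t) for t in range(self.k)]


#: Fixed 5.8S pairing constraints ("F i j k" settings).
R58S_CONSTRAINTS = (
    HelixConstraint("B4", 38, 98, 3),
    HelixConstraint("B5", 41, 54, 3),
    HelixConstraint("B6", 62, 89, 3),
    HelixConstraint("B7", 103, 111, 3),
    HelixConstraint("B8a", 112, 135, 4),
    HelixConstraint("B8b", 119, 128, 3),
)

#: largest position touched by any constraint
R58S_MIN_LENGTH = max(c.j for c in R58S_CONSTRAINTS)

#: every 5' or 3' position prescribed by some constraint (1-based)
CONSTRAINED_POSITIONS = frozenset(
    pos for c in R58S_CONSTRAINTS for ij in c.prescribed_pairs() for pos in ij
)


def check_58s_constraints(r58s_seq: str) -> dict[str, bool]:
    """Per-helix satisfiability of the fixed 5.8S pairing constraints."""
    if len(r58s_seq) < R58S_MIN_LENGTH:
        raise Region58SError(
            f"5.8S too short for constraint check ({len(r58s_seq)} nt < {R58S_MIN_LENGTH})"
        )
    result: dict[str, bool] = {}
    for c in R58S_CONSTRAINTS:
        ok = all(
            can_pair(r58s_seq[i - 1], r58s_seq[j - 1]) for i, j in c.prescribed_pairs()
        )
        result[c.name] = ok
    return result


def structure_report(its2_seq: str, r58s_seq: str) -> StructureReport:
    """Full structure screen for one record."""
    try:
        fold = fold_its2(its2_seq)
        report = check_its2_topology(fold, its2_seq)
    except FoldingError:
        report = StructureReport()
    try:
        report.r58s_constraints = check_58s_constraints(r58s_seq)
    except Region58SError as exc:
        report.r58s_error = str(exc)
    return report
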