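"""Per-region composition statistics: lengths, GC, identity, diversity."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .records import ItsRecord, MsaBlock, RegionAnnotation

REGIONS = ("ITS1", "5.8S", "ITS2", "total")


class UndefinedValueError(ValueError):
    """Raised when a statistic has an empty denominator."""


def gc_content(seq: str) -> float:
    """(G + C) / (A + C + G + T); N and gaps excluded from both sides."""
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise UndefinedValueError("GC content undefined: no A/C/G/T bases")
    return (counts["G"] + counts["C"]) / denom


def percent_identity(row_a: str, row_b: str) -> float:
    """Percent identity over compared alignment columns.

    Compared columns exclude gap-vs-gap and any column with N in either
    row; gap-vs-base counts as a mismatch.  The raw (unrounded) percentage
    is returned; round only at presentation.
    """
    if len(row_a) != len(row_b):
        raise ValueError(f"rows differ in length: {len(row_a)} vs {len(row_b)}")
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
        raise UndefinedValueError("percent identity undefined: zero compared columns")
    return 100.0 * matches / compared


@dataclass
class CompositionReport:
    """Lengths and GC per region for one record."""

    record_id: str
    length: dict[str, int] = field(default_factory=dict)
    gc: dict[str, float] = field(default_factory=dict)


def composition_report(record: ItsRecord, annotation: RegionAnnotation) -> CompositionReport:
    annotation.validate_for(record)
    report = CompositionReport(record_id=record.id)
    for region, (s, e) in annotation.items():
        sub = record.subregion(s, e)
        report.length[region] = e - s + 1
        report.gc[region] = gc_content(sub)
    total = record.subregion(annotation.its1[0], annotation.its2[1])
    report.length["total"] = annotation.its2[1] - annotation.its1[0] + 1
    report.gc["total"] = gc_content(total)
    return report


@dataclass(frozen=True)
class IdentityMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray  # percent, symmetric, diagonal 100

    def value(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def identity_matrix(msa: MsaBlock) -> IdentityMatrix:
    n = msa.n_rows
    mat = np.full((n, n), 100.0)
    for i, j in combinations(range(n), 2):
        pid = percent_identity(msa.rows[i], msa.rows[j])
        mat[i, j] = mat[j, i] = pid
    return IdentityMatrix(labels=tuple(msa.labels), matrix=mat)


@dataclass(frozen=True)
class DiversityEstimate:
    pi: float
    n_sequences: int
    n_sites: int


def nucleotide_diversity(msa: MsaBlock) -> DiversityEstimate:
    """Average pairwise proportion of differing sites, pairwise deletion.

    For every unordered row pair, sites with a gap or N in either row are
    dropped for that pair; pi averages (differences / compared sites) over
    all pairs.
    """
    if msa.n_rows < 2:
        raise ValueError("nucleotide diversity needs at least 2 rows")
    total = 0.0
    for i, j in combinations(range(msa.n_rows), 2):
        diffs = compared = 0
        for x, y in zip(msa.rows[i], msa.rows[j]):
            if x in "-N" or y in "-N":
                continue
            compared += 1
            if x != y:
                diffs += 1
        if compared == 0:
            raise UndefinedValueError(
                f"pair ({msa.labels[i]!r}, {msa.labels[j]!r}) has zero compared sites"
            )
        total += diffs / compared
    n_pairs = msa.n_rows * (msa.n_rows - 1) // 2
    return DiversityEstimate(
        pi=total / n_pairs, n_sequences=msa.n_rows, n_sites=msa.n_cols
    )
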