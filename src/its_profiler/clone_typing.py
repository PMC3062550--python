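"""Collapse a clone library into distinct ITS types with majority consensus.

Clones are multiple-aligned, single-linkage clustered at an identity
threshold (default 99%), small clusters are absorbed into their nearest
neighbor as putative PCR/cloning singletons, and each cluster is collapsed
to a column-majority consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from . import align
from .composition import percent_identity
from .records import ItsRecord, MsaBlock

logger = logging.getLogger(__name__)

DEFAULT_MIN_TYPE_IDENTITY = 99.0
DEFAULT_MIN_MEMBERS = 2


@dataclass
class ItsType:
    consensus: ItsRecord
    members: list[str]

    @property
    def support(self) -> int:
        return len(self.members)


@dataclass
class ItsTypeSet:
    accession: str
    types: list[ItsType] = field(default_factory=list)
    absorbed_singletons: list[str] = field(default_factory=list)


def align_set(records: list[ItsRecord]) -> MsaBlock:
    """Progressive multiple alignment of a clone set (canonical id order)."""
    if len(records) < 2:
        raise ValueError("align_set needs at least 2 records")
    short = [r.id for r in records if len(r.sequence) < 300]
    if short:
        raise ValueError(f"records below 300 nt: {', '.join(short)}")
    return align.progressive_align(records)


def _majority_consensus(rows: list[str], first_seen_order: list[str]) -> str:
    """Column-wise majority; gap-majority columns dropped; ties broken by
    the base observed first in column scan order."""
    out = []
    for j in range(len(rows[0])):
        column = [row[j] for row in rows]
        counts: dict[str, int] = {}
        for ch in column:
            counts[ch] = counts.get(ch, 0) + 1
        gap_count = counts.get("-", 0)
        if gap_count > len(rows) / 2:
            continue
        counts.pop("-", None)
        if not counts:
            continue
        best_n = max(counts.values())
        winner = next(ch for ch in column if ch != "-" and counts[ch] == best_n)
        out.append(winner)
    return "".join(out)


def cluster_types(
    msa: MsaBlock,
    accession: str = "unknown",
    min_type_identity: float = DEFAULT_MIN_TYPE_IDENTITY,
    min_members: int = DEFAULT_MIN_MEMBERS,
) -> ItsTypeSet:
    """Single-linkage clustering of aligned clones into ITS types."""
    if not (90.0 < min_type_identity <= 100.0):
        raise ValueError(
            f"min_type_identity must be in (90, 100], got {min_type_identity}"
        )
    n = msa.n_rows
    if n == 1:
        rec = ItsRecord(
            id=f"{accession}con1", sequence=msa.ungapped(msa.labels[0]),
            source="consensus", accession_meta={"accession": accession},
        )
        return ItsTypeSet(accession, [ItsType(rec, list(msa.labels))])

    dist = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = 100.0 - percent_identity(msa.rows[i], msa.rows[j])
        dist[i, j] = dist[j, i] = d
    threshold = 100.0 - min_type_identity

    Z = linkage(dist[np.triu_indices(n, k=1)], method="single")
    assignment = fcluster(Z, t=threshold, criterion="distance")

    clusters: dict[int, list[int]] = {}
    for idx, c in enumerate(assignment):
        clusters.setdefault(int(c), []).append(idx)

    # absorb putative PCR/cloning singleton clusters into the nearest cluster
    absorbed: list[str] = []
    small = [c for c, members in clusters.items() if len(members) < min_members]
    big = [c for c in clusters if c not in small]
    if big:
        for c in small:
            members = clusters.pop(c)
            best_cluster, best_d = None, np.inf
            for other in big:
                d = float(
                    np.mean([dist[i, j] for i in members for j in clusters[other]])
                )
                if d < best_d:
                    best_cluster, best_d = other, d
            clusters[best_cluster].extend(members)
            for i in members:
                absorbed.append(msa.labels[i])
                logger.info(
                    "absorbed singleton clone %s into cluster %s",
                    msa.labels[i], best_cluster,
                )

    types: list[ItsType] = []
    ordered = sorted(
        clusters.values(), key=lambda m: (-len(m), min(msa.labels[i] for i in m))
    )
    for k, members in enumerate(ordered, start=1):
        members = sorted(members)
        consensus_seq = _majority_consensus(
            [msa.rows[i] for i in members], [msa.labels[i] for i in members]
        )
        rec = ItsRecord(
            id=f"{accession}con{k}",
            sequence=consensus_seq,
            source="consensus",
            accession_meta={"accession": accession, "n_members": str(len(members))},
        )
        types.append(ItsType(rec, [msa.labels[i] for i in members]))
    return ItsTypeSet(accession=accession, types=types, absorbed_singletons=absorbed)


def type_clones(
    records: list[ItsRecord],
    accession: str = "unknown",
    min_type_identity: float = DEFAULT_MIN_TYPE_IDENTITY,
    min_members: int = DEFAULT_MIN_MEMBERS,
) -> ItsTypeSet:
    """Convenience: align a clone library and cluster it into types."""
    msa = align_set(records)
    return cluster_types(msa, accession, min_type_identity, min_members)
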