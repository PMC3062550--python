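"""TSV serialization for stage reports (regions, composition, motifs,
structure, verdicts, assignments, read depth)."""

from __future__ import annotations

import csv
import os

import numpy as np

from .composition import CompositionReport, DiversityEstimate, IdentityMatrix
from .folding import StructureReport
from .motifs import MotifReport
from .phylogeny import GenomeAssignment
from .pseudogene import PseudogeneVerdict
from .records import RegionAnnotation

PathLike = str | os.PathLike


def _write_tsv(path: PathLike, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def _read_tsv(path: PathLike) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


# -- regions ---------------------------------------------------------------

REGION_COLUMNS = [
    "id", "its1_start", "its1_end", "r58s_start", "r58s_end",
    "its2_start", "its2_end", "score",
]


def write_regions(path: PathLike, rows: list[tuple[str, RegionAnnotation, float]]) -> None:
    _write_tsv(path, REGION_COLUMNS, [
        [rid, a.its1[0], a.its1[1], a.r58s[0], a.r58s[1], a.its2[0], a.its2[1],
         f"{score:.2f}"]
        for rid, a, score in rows
    ])


def read_regions(path: PathLike) -> dict[str, RegionAnnotation]:
    out: dict[str, RegionAnnotation] = {}
    for row in _read_tsv(path):
        out[row["id"]] = RegionAnnotation(
            its1=(int(row["its1_start"]), int(row["its1_end"])),
            r58s=(int(row["r58s_start"]), int(row["r58s_end"])),
            its2=(int(row["its2_start"]), int(row["its2_end"])),
        )
    return out


# -- composition -----------------------------------------------------------

def write_composition(path: PathLike, reports: list[CompositionReport]) -> None:
    header = ["id"]
    for region in ("ITS1", "5.8S", "ITS2", "total"):
        header += [f"{region}_length", f"{region}_gc"]
    rows = []
    for rep in reports:
        row: list = [rep.record_id]
        for region in ("ITS1", "5.8S", "ITS2", "total"):
            row += [rep.length[region], f"{rep.gc[region]:.6f}"]
        rows.append(row)
    _write_tsv(path, header, rows)


def read_composition(path: PathLike) -> list[CompositionReport]:
    out = []
    for row in _read_tsv(path):
        rep = CompositionReport(record_id=row["id"])
        for region in ("ITS1", "5.8S", "ITS2", "total"):
            rep.length[region] = int(row[f"{region}_length"])
            rep.gc[region] = float(row[f"{region}_gc"])
        out.append(rep)
    return out


# -- identity / diversity --------------------------------------------------

def write_identity_matrix(path: PathLike, im: IdentityMatrix) -> None:
    header = ["id"] + list(im.labels)
    rows = [
        [lab] + [f"{im.matrix[i, j]:.2f}" for j in range(len(im.labels))]
        for i, lab in enumerate(im.labels)
    ]
    _write_tsv(path, header, rows)


def write_diversity(path: PathLike, est: DiversityEstimate) -> None:
    _write_tsv(path, ["pi", "n_sequences", "n_sites"],
               [[f"{est.pi:.6f}", est.n_sequences, est.n_sites]])


# -- motifs ----------------------------------------------------------------

MOTIF_COLUMNS = ["id", "motif", "start", "n_mismatches", "positions", "bases",
                 "indel_flag"]


def write_motifs(path: PathLike, rows: list[tuple[str, MotifReport]]) -> None:
    _write_tsv(path, MOTIF_COLUMNS, [
        [rid, m.motif, m.best_start, m.n_mismatches,
         ",".join(map(str, m.mismatch_positions)), ",".join(m.mismatch_bases),
         int(m.indel_flag)]
        for rid, m in rows
    ])


def read_motifs(path: PathLike) -> dict[str, dict[str, MotifReport]]:
    out: dict[str, dict[str, MotifReport]] = {}
    for row in _read_tsv(path):
        positions = [int(x) for x in row["positions"].split(",") if x]
        bases = [x for x in row["bases"].split(",") if x]
        rep = MotifReport(
            motif=row["motif"], best_start=int(row["start"]),
            mismatch_positions=positions, mismatch_bases=bases,
            indel_flag=bool(int(row["indel_flag"])),
        )
        out.setdefault(row["id"], {})[row["motif"]] = rep
    return out


# -- structure -------------------------------------------------------------

STRUCTURE_COLUMNS = ["id", "its2_n_helices", "tggt_in_helix3",
                     "pyr_pyr_bulge_helix2", "r58s_failed", "r58s_error",
                     "overall_its2_ok", "overall_58s_ok"]


def write_structure(path: PathLike, rows: list[tuple[str, StructureReport]]) -> None:
    out = []
    for rid, rep in rows:
        failed = ",".join(sorted(k for k, v in rep.r58s_constraints.items() if not v))
        out.append([
            rid, rep.its2_n_helices, int(rep.tggt_in_helix3),
            int(rep.pyr_pyr_bulge_helix2), failed, rep.r58s_error or "",
            int(rep.overall_its2_ok), int(rep.overall_58s_ok),
        ])
    _write_tsv(path, STRUCTURE_COLUMNS, out)


def read_structure(path: PathLike) -> dict[str, StructureReport]:
    from .folding import R58S_CONSTRAINTS

    out: dict[str, StructureReport] = {}
    for row in _read_tsv(path):
        failed = set(row["r58s_failed"].split(",")) if row["r58s_failed"] else set()
        rep = StructureReport(
            its2_n_helices=int(row["its2_n_helices"]),
            tggt_in_helix3=bool(int(row["tggt_in_helix3"])),
            pyr_pyr_bulge_helix2=bool(int(row["pyr_pyr_bulge_helix2"])),
            r58s_error=row["r58s_error"] or None,
        )
        if rep.r58s_error is None:
            rep.r58s_constraints = {
                c.name: c.name not in failed for c in R58S_CONSTRAINTS
            }
        out[row["id"]] = rep
    return out


# -- verdicts / assignments / depth ---------------------------------------

def write_verdicts(path: PathLike, verdicts: list[PseudogeneVerdict]) -> None:
    _write_tsv(path, ["id", "status", "evidence"], [
        [v.record_id, v.status.value, ";".join(v.evidence)] for v in verdicts
    ])


def write_assignments(path: PathLike, assignments: list[GenomeAssignment]) -> None:
    _write_tsv(path, ["id", "genome", "margin", "ambiguous", "mean_distances"], [
        [a.query_id, a.genome, f"{a.margin:.6f}", int(a.ambiguous),
         ";".join(f"{g}={d:.6f}" for g, d in sorted(a.mean_distances.items()))]
        for a in assignments
    ])


def write_depth(path: PathLike, depth: np.ndarray) -> None:
    _write_tsv(path, ["position", "depth"],
               [[i + 1, int(d)] for i, d in enumerate(depth)])
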