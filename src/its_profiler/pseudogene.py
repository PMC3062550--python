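"""Putative-pseudogene classification from composition, motif and structure evidence.

Decision rule: any motif mismatch, a failed ITS2 four-helix/TGGT check, or a
failed 5.8S pairing-constraint check makes a record a putative pseudogene
(sequence-intrinsic evidence); cohort-relative anomalies alone (low GC,
aberrant ITS1 length) only raise it to "suspect".
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from enum import Enum

from .composition import CompositionReport
from .folding import StructureReport
from .motifs import MotifReport


class Status(str, Enum):
    FUNCTIONAL = "functional"
    SUSPECT = "suspect"
    PUTATIVE_PSEUDOGENE = "putative_pseudogene"


@dataclass
class PseudogeneVerdict:
    record_id: str
    status: Status
    evidence: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)


DEFAULT_GC_Z_THRESHOLD = -2.0
DEFAULT_LENGTH_SLACK = 5  # nt beyond cohort ITS1 min/max


class CohortError(ValueError):
    pass


def classify(
    comp: CompositionReport,
    motif_reports: dict[str, MotifReport],
    struct: StructureReport,
    cohort: list[CompositionReport] | None = None,
    gc_z_threshold: float = DEFAULT_GC_Z_THRESHOLD,
    length_slack: int = DEFAULT_LENGTH_SLACK,
    use_gc_rule: bool = True,
) -> PseudogeneVerdict:
    """Combine the three reports into a verdict.

    `cohort` holds composition reports of functional candidates used for
    GC z-scoring and ITS1-length bounds; required when `use_gc_rule` is on.
    """
    evidence: list[str] = []

    for name in ("M1", "M2", "M3"):
        rep = motif_reports.get(name)
        if rep is not None and (rep.n_mismatches >= 1 or rep.indel_flag):
            evidence.append(f"motif_disruption({name})")
    if not struct.overall_its2_ok:
        evidence.append("its2_fold_fail")
    if struct.r58s_error is not None:
        evidence.append("r58s_constraint_fail(length)")
    else:
        failed = sorted(k for k, ok in struct.r58s_constraints.items() if not ok)
        if failed:
            evidence.append(f"r58s_constraint_fail({','.join(failed)})")

    if evidence:
        status = Status.PUTATIVE_PSEUDOGENE
    else:
        soft: list[str] = []
        if use_gc_rule:
            if not cohort:
                raise CohortError(
                    "GC rule enabled but cohort is empty; supply a functional "
                    "cohort or disable the rule"
                )
            gcs = [c.gc["total"] for c in cohort]
            mean = statistics.fmean(gcs)
            sd = statistics.pstdev(gcs)
            if sd > 0:
                z = (comp.gc["total"] - mean) / sd
                if z < gc_z_threshold:
                    soft.append("low_gc")
            lens = [c.length["ITS1"] for c in cohort]
            its1_len = comp.length["ITS1"]
            if its1_len < min(lens) - length_slack or its1_len > max(lens) + length_slack:
                soft.append("length_anomaly")
        status = Status.SUSPECT if soft else Status.FUNCTIONAL
        evidence = soft

    return PseudogeneVerdict(
        record_id=comp.record_id,
        status=status,
        evidence=evidence,
        parameters={
            "gc_z_threshold": gc_z_threshold,
            "length_slack": length_slack,
            "use_gc_rule": use_gc_rule,
        },
    )


def cpg_transition_excess(
    seq: str, template: str, min_count: int = 3, min_fraction: float = 0.5
) -> tuple[int, bool]:
    """Count CpG-deamination transitions of `seq` relative to an aligned
    functional `template` (C->T at the C of a template CpG; G->A at a G
    preceded by C in the template).

    Returns (count, flag); flag is set when the deamination count makes up
    more than `min_fraction` of all substitutions and is at least
    `min_count`.
    """
    if len(seq) != len(template):
        raise ValueError("seq and template must be aligned (same gapped length)")

    # template CpG adjacency over non-gap columns
    nongap_cols = [c for c, ch in enumerate(template) if ch != "-"]
    is_cpg_c = set()
    is_cpg_g = set()
    for a, b in zip(nongap_cols, nongap_cols[1:]):
        if template[a] == "C" and template[b] == "G":
            is_cpg_c.add(a)
            is_cpg_g.add(b)

    count = total_subs = 0
    for c, (t, s) in enumerate(zip(template, seq)):
        if t in "-N" or s in "-N":
            continue
        if t != s:
            total_subs += 1
            if (c in is_cpg_c and s == "T") or (c in is_cpg_g and s == "A"):
                count += 1
    flag = count >= min_count and total_subs > 0 and count / total_subs > min_fraction
    return count, flag
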