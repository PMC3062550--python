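"""Seeded synthetic-data generator.

Builds functional ITS1-5.8S-ITS2 templates whose 5.8S carries the three
canonical motifs and satisfies all six pairing constraints, and whose ITS2
is a four-stem-loop design that folds into four helices with TGGT in the
third and a pyrimidine-pyrimidine internal loop in the second — all by
construction.  Operators derive pseudogenized copies (CpG deamination,
targeted motif hits, helix breaks, indels including a 41-nt ITS1 deletion),
clone libraries with per-base error, hybrid accessions mixing parental
types, and shotgun-style reads over a contig.  Everything is driven by
numpy Generators, so a fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .coverage import Placement, reverse_complement
from .folding import R58S_CONSTRAINTS
from .motifs import CANONICAL_MOTIFS, MotifDefinition
from .records import ItsRecord, RegionAnnotation
from .trees import PhyloTree, TreeNode

_BASES = np.array(list("ACGT"))

#: fixed stream for conserved sequence shared by all seeds (5.8S filler, flanks)
_CONSERVED_SEED = 9158


# ---------------------------------------------------------------------------
# 5.8S design
# ---------------------------------------------------------------------------

#: 1-based motif placements within the synthetic 5.8S (collision-free with
#: every constrained position).
R58S_MOTIF_OFFSETS = {"M1": 10, "M2": 66, "M3": 140}
R58S_LENGTH = 155


def _constrained_positions() -> set[int]:
    out: set[int] = set()
    for c in R58S_CONSTRAINTS:
        for i, j in c.prescribed_pairs():
            out.update((i, j))
    return out


_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


def design_58s(rng: np.random.Generator, gc_filler: float = 0.53) -> str:
    """A 155-nt 5.8S with exact M1/M2/M3 and all constraints satisfiable."""
    seq = [None] * R58S_LENGTH
    for motif in CANONICAL_MOTIFS:
        off = R58S_MOTIF_OFFSETS[motif.name]
        for k, ch in enumerate(motif.canonical):
            seq[off - 1 + k] = ch
    for c in R58S_CONSTRAINTS:
        for i, j in c.prescribed_pairs():
            if seq[i - 1] is None:
                seq[i - 1] = _draw_base(rng, gc_filler)
            seq[j - 1] = _WC[seq[i - 1]]
    for k in range(R58S_LENGTH):
        if seq[k] is None:
            seq[k] = _draw_base(rng, gc_filler)
    return "".join(seq)


def _draw_base(rng: np.random.Generator, gc: float) -> str:
    pools = "GC" if rng.random() < gc else "AT"
    return pools[rng.integers(2)]


# ---------------------------------------------------------------------------
# ITS2 design: four stem-loop cassettes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Its2Design:
    sequence: str
    #: (start5_arm, loop_start, loop_end, end3_arm), 1-based within ITS2
    cassettes: tuple[tuple[int, int, int, int], ...]


def design_its2(target_length: int = 210) -> Its2Design:
    """Deterministic four-cassette ITS2 with TGGT in cassette III and a
    C/C internal loop in cassette II; linkers and tail are unpairable A runs."""
    # Stem polarity alternates (G-rich arm first in I/III, C-rich first in
    # II/IV) so bases facing each other across the A-linkers cannot pair;
    # with all pairable bases confined to stems, the local four-hairpin
    # layout is the unique maximum-pairing, minimum-span structure.
    link = "AAAAA"
    c1 = "GGCGC" + "AAAA" + "GCGCC"
    c2 = "CGT" + "C" + "GCC" + "AAAA" + "GGC" + "C" + "ACG"
    c3 = "GTGGTG" + "AAAA" + "CACCAC"
    c4 = "CGGCG" + "AAAA" + "CGCCG"
    parts = [link, c1, link, c2, link, c3, link, c4]
    fixed = sum(len(p) for p in parts)
    if target_length < fixed:
        raise ValueError(f"ITS2 target length {target_length} < design minimum {fixed}")
    seq = "".join(parts) + "A" * (target_length - fixed)

    cassettes = []
    pos = len(link)
    for cas in (c1, c2, c3, c4):
        start = pos + 1
        end = pos + len(cas)
        # loop bounds: interior between the two arms
        arm = {id(c1): 5, id(c2): 7, id(c3): 6, id(c4): 5}[id(cas)]
        cassettes.append((start, start + arm, end - arm, end))
        pos = end + len(link)
    return Its2Design(sequence=seq, cassettes=tuple(cassettes))


DEFAULT_ITS2_DESIGN = design_its2()


# ---------------------------------------------------------------------------
# Lineage specification
# ---------------------------------------------------------------------------

@dataclass
class Lineage:
    """A node of the lineage tree; `divergence` is the per-mutable-site
    substitution probability on the branch leading to this node."""

    name: str
    divergence: float = 0.0
    children: list["Lineage"] = field(default_factory=list)

    def leaves(self) -> list["Lineage"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def default_lineage() -> Lineage:
    """Seven leaves mirroring the study's genome groups."""
    return Lineage("root", 0.0, [
        Lineage("Ensete", 0.10),
        Lineage("musoid", 0.02, [
            Lineage("T", 0.04),
            Lineage("rhodo_core", 0.02, [
                Lineage("Rhodochlamys", 0.03),
                Lineage("core", 0.01, [
                    Lineage("S", 0.025),
                    Lineage("ab", 0.01, [
                        Lineage("A", 0.02),
                        Lineage("B", 0.02),
                    ]),
                ]),
            ]),
        ]),
    ])


@dataclass
class SyntheticSpec:
    seed: int = 0
    lineage: Lineage = field(default_factory=default_lineage)
    its1_length: int = 220
    its2_length: int = 210
    flank5: int = 40
    flank3: int = 40
    gc_its1: float = 0.60
    gc_flank: float = 0.50
    gc_58s_filler: float = 0.53

    def __post_init__(self) -> None:
        for leaf in self.lineage.leaves():
            if not (0 <= leaf.divergence < 0.75):
                raise ValueError(
                    f"divergence {leaf.divergence} for {leaf.name!r} outside [0, 0.75)"
                )


@dataclass
class TemplateSet:
    records: list[ItsRecord]
    annotation: RegionAnnotation  # identical for all templates (no indels)
    true_tree: PhyloTree
    mutable_positions: list[int]  # 0-based positions free to vary (ITS1)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    return "".join(_draw_base(rng, gc) for _ in range(length))


def _lineage_to_phylo(node: Lineage) -> TreeNode:
    t = TreeNode(label=node.name if not node.children else None,
                 length=node.divergence)
    for c in node.children:
        t.children.append(_lineage_to_phylo(c))
    return t


def generate_templates(spec: SyntheticSpec) -> TemplateSet:
    """One functional template per lineage leaf.

    The root amplicon is flank5 + ITS1 + 5.8S + ITS2 + flank3; branches
    apply i.i.d. substitutions to ITS1 positions only, so the conserved
    5.8S/ITS2 designs survive in every leaf and each template is
    functional by construction.
    """
    rng = np.random.default_rng(spec.seed)
    its1 = _random_seq(rng, spec.its1_length, spec.gc_its1)
    # 5.8S filler and the 18S/26S flanks are conserved sequence in reality:
    # draw them from a fixed stream so every seed shares them and any
    # synthetic record delimits against the packaged reference.
    conserved = np.random.default_rng(_CONSERVED_SEED)
    r58s = design_58s(conserved, spec.gc_58s_filler)
    its2 = design_its2(spec.its2_length).sequence
    f5 = _random_seq(conserved, spec.flank5, spec.gc_flank)
    f3 = _random_seq(conserved, spec.flank3, spec.gc_flank)
    root_seq = f5 + its1 + r58s + its2 + f3

    s1 = spec.flank5 + 1
    annotation = RegionAnnotation(
        its1=(s1, s1 + spec.its1_length - 1),
        r58s=(s1 + spec.its1_length, s1 + spec.its1_length + R58S_LENGTH - 1),
        its2=(
            s1 + spec.its1_length + R58S_LENGTH,
            s1 + spec.its1_length + R58S_LENGTH + spec.its2_length - 1,
        ),
    )
    mutable = list(range(annotation.its1[0] - 1, annotation.its1[1]))

    leaves: dict[str, str] = {}

    def descend(node: Lineage, seq: str) -> None:
        seq = _mutate(rng, seq, node.divergence, mutable)
        if not node.children:
            leaves[node.name] = seq
        for child in node.children:
            descend(child, seq)

    descend(spec.lineage, root_seq)

    records = [
        ItsRecord(id=name, sequence=seq, source="direct",
                  accession_meta={"genome": name})
        for name, seq in leaves.items()
    ]
    tree = PhyloTree(root=_lineage_to_phylo(spec.lineage), rooted=True)
    return TemplateSet(
        records=records, annotation=annotation, true_tree=tree,
        mutable_positions=mutable,
    )


def _mutate(rng: np.random.Generator, seq: str, p: float,
            positions: list[int]) -> str:
    if p <= 0 or not positions:
        return seq
    arr = list(seq)
    hits = np.asarray(positions)[rng.random(len(positions)) < p]
    for pos in hits:
        current = arr[pos]
        others = [b for b in "ACGT" if b != current]
        arr[pos] = others[rng.integers(3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# Pseudogenization operator
# ---------------------------------------------------------------------------

@dataclass
class PseudogenizeParams:
    cpg_rate: float = 0.0
    #: (motif name, 1-based position within motif, replacement base)
    motif_hits: list[tuple[str, int, str]] = field(default_factory=list)
    break_helices: list[str] = field(default_factory=list)
    break_its2: bool = False
    #: (0-based offset within ITS1, deleted length); classic case is 41 nt
    its1_deletion: Optional[tuple[int, int]] = None


_BREAK_BASE = {"T": "C", "A": "C", "C": "A", "G": "A"}  # never canonical with key


@dataclass
class PseudogenizedRecord:
    record: ItsRecord
    annotation: RegionAnnotation
    truth: dict


def pseudogenize(
    template: ItsRecord,
    annotation: RegionAnnotation,
    params: PseudogenizeParams,
    rng: np.random.Generator | None = None,
    new_id: str | None = None,
) -> PseudogenizedRecord:
    """Apply the requested defects to a functional template."""
    rng = rng or np.random.default_rng(0)
    arr = list(template.sequence)
    truth: dict = {"defects": []}
    motif_by_name = {m.name: m for m in CANONICAL_MOTIFS}
    r58s_start = annotation.r58s[0] - 1  # 0-based

    # locate all motifs in the pristine template before mutating anything
    region = "".join(arr[r58s_start : annotation.r58s[1]])
    motif_starts: dict[str, int] = {}
    for name, pos, base in params.motif_hits:
        motif: MotifDefinition = motif_by_name[name]
        if name not in motif_starts:
            hit = region.find(motif.canonical)
            if hit < 0:
                raise ValueError(
                    f"motif {name} not present exactly in template {template.id!r}"
                )
            motif_starts[name] = hit
        if not (1 <= pos <= len(motif.canonical)):
            raise ValueError(f"position {pos} outside motif {name}")
        arr[r58s_start + motif_starts[name] + pos - 1] = base
        truth["defects"].append(f"motif:{name}@{pos}->{base}")

    constraint_by_name = {c.name: c for c in R58S_CONSTRAINTS}
    for hname in params.break_helices:
        c = constraint_by_name[hname]
        i, j = c.prescribed_pairs()[0]
        partner = arr[r58s_start + j - 1]
        arr[r58s_start + i - 1] = _BREAK_BASE[partner]
        truth["defects"].append(f"helix:{hname}")

    if params.break_its2:
        design = DEFAULT_ITS2_DESIGN
        its2_start = annotation.its2[0] - 1
        arm_start, _, _, arm_end = design.cassettes[0]
        for k in range(arm_start, arm_end + 1):  # wipe cassette I entirely
            arr[its2_start + k - 1] = "A"
        truth["defects"].append("its2_break")

    if params.cpg_rate > 0:
        n_deaminated = 0
        for k in range(len(arr) - 1):
            if arr[k] == "C" and arr[k + 1] == "G":
                if rng.random() < params.cpg_rate:
                    arr[k] = "T"
                    n_deaminated += 1
                if rng.random() < params.cpg_rate:
                    arr[k + 1] = "A"
                    n_deaminated += 1
        truth["cpg_deaminated"] = n_deaminated
        if n_deaminated:
            truth["defects"].append("cpg")

    new_annotation = annotation
    if params.its1_deletion is not None:
        offset, length = params.its1_deletion
        its1_s, its1_e = annotation.its1
        if offset + length > its1_e - its1_s + 1:
            raise ValueError("ITS1 deletion extends beyond ITS1")
        start0 = its1_s - 1 + offset
        del arr[start0 : start0 + length]
        new_annotation = RegionAnnotation(
            its1=(its1_s, its1_e - length),
            r58s=(annotation.r58s[0] - length, annotation.r58s[1] - length),
            its2=(annotation.its2[0] - length, annotation.its2[1] - length),
        )
        truth["defects"].append(f"its1_del:{length}")

    rec = ItsRecord(
        id=new_id or f"{template.id}_psi",
        sequence="".join(arr),
        source=template.source,
        accession_meta=dict(template.accession_meta),
    )
    return PseudogenizedRecord(record=rec, annotation=new_annotation, truth=truth)


#: offset used for the classic 41-nt ITS1 deletion (mid-ITS1)
CLASSIC_DELETION = (80, 41)


# ---------------------------------------------------------------------------
# Clone libraries, hybrids, reads
# ---------------------------------------------------------------------------

def fixed_variant(
    template: ItsRecord,
    annotation: RegionAnnotation,
    n_diffs: int,
    seed: int = 0,
    new_id: str | None = None,
) -> ItsRecord:
    """A copy of `template` with exactly `n_diffs` substitutions at distinct
    ITS1 positions — handy for scenarios needing a controlled divergence."""
    rng = np.random.default_rng(seed)
    s, e = annotation.its1
    positions = rng.choice(np.arange(s - 1, e), size=n_diffs, replace=False)
    arr = list(template.sequence)
    for pos in positions:
        current = arr[pos]
        others = [b for b in "ACGT" if b != current]
        arr[pos] = others[rng.integers(3)]
    return ItsRecord(
        id=new_id or f"{template.id}_v{n_diffs}",
        sequence="".join(arr),
        source=template.source,
        accession_meta=dict(template.accession_meta),
    )


def simulate_clones(
    templates: list[ItsRecord],
    n_clones: int,
    error_rate: float,
    mixture_weights: list[float] | None = None,
    seed: int = 0,
    counts: list[int] | None = None,
) -> tuple[list[ItsRecord], dict[str, str]]:
    """Draw a clone library from one or more templates with i.i.d. per-base
    error.  Returns (clones, truth) where truth maps clone id -> template id.

    `counts` fixes the exact number of clones per template; otherwise
    `mixture_weights` (default uniform) are sampled.
    """
    rng = np.random.default_rng(seed)
    if error_rate < 0 or error_rate > 0.01:
        raise ValueError("error_rate must be within [0, 1%]")
    if counts is not None:
        if len(counts) != len(templates) or sum(counts) != n_clones:
            raise ValueError("counts must match templates and sum to n_clones")
        origin = [i for i, c in enumerate(counts) for _ in range(c)]
    else:
        if mixture_weights is None:
            mixture_weights = [1.0 / len(templates)] * len(templates)
        if abs(sum(mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture_weights must sum to 1")
        origin = list(rng.choice(len(templates), size=n_clones, p=mixture_weights))

    clones: list[ItsRecord] = []
    truth: dict[str, str] = {}
    for k, t_idx in enumerate(origin, start=1):
        template = templates[int(t_idx)]
        seq = _mutate(rng, template.sequence, error_rate,
                      list(range(len(template.sequence))))
        cid = f"clone{k:03d}"
        clones.append(
            ItsRecord(id=cid, sequence=seq, source="clone",
                      accession_meta={"template": template.id})
        )
        truth[cid] = template.id
    return clones, truth


def hybrid_types(
    templates: dict[str, ItsRecord],
    composition: dict[str, int],
    divergence: float = 0.005,
    seed: int = 0,
    prefix: str = "hyb",
) -> tuple[list[ItsRecord], dict[str, str]]:
    """Derive ITS types of a synthetic hybrid accession.

    `composition` maps parental genome label -> number of derived types,
    e.g. ``{"B": 1, "A": 2}``; each type is the parental template with a
    light sprinkle of substitutions.  Returns (types, truth labels).
    """
    rng = np.random.default_rng(seed)
    out: list[ItsRecord] = []
    truth: dict[str, str] = {}
    k = 0
    for genome in sorted(composition):
        template = templates[genome]
        for _ in range(composition[genome]):
            k += 1
            seq = _mutate(rng, template.sequence, divergence,
                          list(range(len(template.sequence))))
            tid = f"{prefix}con{k}"
            out.append(ItsRecord(id=tid, sequence=seq, source="consensus",
                                 accession_meta={"true_genome": genome}))
            truth[tid] = genome
    return out, truth


def simulate_reads(
    contig: ItsRecord,
    coverage: float,
    read_len: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[ItsRecord], list[Placement]]:
    """Uniform shotgun reads over a contig, both strands, i.i.d. errors."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    L = len(contig.sequence)
    if read_len > L:
        raise ValueError("read_len must not exceed contig length")
    rng = np.random.default_rng(seed)
    n_reads = max(1, round(coverage * L / read_len))
    reads: list[ItsRecord] = []
    placements: list[Placement] = []
    for k in range(1, n_reads + 1):
        start = int(rng.integers(0, L - read_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = contig.sequence[start : start + read_len]
        seq = _mutate(rng, seq, error_rate, list(range(read_len)))
        if strand == "-":
            seq = reverse_complement(seq)
        rid = f"read{k:05d}"
        reads.append(ItsRecord(id=rid, sequence=seq, source="read"))
        placements.append(
            Placement(read_id=rid, start=start + 1, end=start + read_len,
                      identity=100.0, strand=strand)
        )
    return reads, placements


# ---------------------------------------------------------------------------
# Packaged reference and benchmark cohorts
# ---------------------------------------------------------------------------

_REFERENCE_SEED = 20110317


def default_reference():
    """Deterministic packaged annotated reference (rice-ITS stand-in)."""
    from .delimit import AnnotatedReference

    spec = SyntheticSpec(seed=_REFERENCE_SEED,
                         lineage=Lineage("root", 0.0, [Lineage("REF", 0.0)]))
    tset = generate_templates(spec)
    rec = replace(tset.records[0], id="synthetic_reference")
    return AnnotatedReference(record=rec, annotation=tset.annotation)


_DEFECT_MENU = (
    PseudogenizeParams(motif_hits=[("M1", 11, "T"), ("M1", 16, "T")]),
    PseudogenizeParams(motif_hits=[("M1", 12, "A")]),
    PseudogenizeParams(motif_hits=[("M2", 9, "T"), ("M2", 14, "G")]),
    PseudogenizeParams(motif_hits=[("M3", 7, "T"), ("M3", 8, "T")]),
    PseudogenizeParams(break_helices=["B4"]),
    PseudogenizeParams(break_helices=["B6", "B8a"]),
    PseudogenizeParams(break_its2=True),
    PseudogenizeParams(motif_hits=[("M2", 9, "T")], cpg_rate=0.3),
    PseudogenizeParams(break_helices=["B7"], cpg_rate=0.3),
    PseudogenizeParams(break_its2=True, its1_deletion=CLASSIC_DELETION),
)


def pseudogene_benchmark(
    seed: int, n_functional: int = 50, n_pseudogene: int = 50
) -> list[tuple[ItsRecord, RegionAnnotation, bool]]:
    """Labeled benchmark: (record, true annotation, is_pseudogene) triples.

    Functional entries are lineage templates with fresh ITS1 variation;
    pseudogenized entries additionally carry a defect drawn from a fixed
    menu of motif hits, helix breaks, ITS2 stem wipes and indels.
    """
    rng = np.random.default_rng(seed)
    tset = generate_templates(SyntheticSpec(seed=seed))
    out: list[tuple[ItsRecord, RegionAnnotation, bool]] = []
    templates = tset.records
    for k in range(n_functional):
        base = templates[int(rng.integers(len(templates)))]
        seq = _mutate(rng, base.sequence, 0.01, tset.mutable_positions)
        rec = ItsRecord(id=f"fun{k:03d}", sequence=seq, source="consensus")
        out.append((rec, tset.annotation, False))
    for k in range(n_pseudogene):
        base = templates[int(rng.integers(len(templates)))]
        seq = _mutate(rng, base.sequence, 0.01, tset.mutable_positions)
        carrier = ItsRecord(id=f"psi{k:03d}", sequence=seq, source="consensus")
        params = _DEFECT_MENU[int(rng.integers(len(_DEFECT_MENU)))]
        psi = pseudogenize(carrier, tset.annotation, params, rng=rng,
                           new_id=carrier.id)
        out.append((psi.record, psi.annotation, True))
    return out
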