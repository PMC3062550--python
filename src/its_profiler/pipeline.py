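"""Pipeline orchestration: delimit -> stats -> motifs -> fold -> classify
-> type -> tree (-> assign) over a directory of inputs, with a run manifest.

Plain files plus a JSON manifest; no workflow engine.  Stages are
deterministic for a fixed config and inputs, so re-running reproduces
identical output hashes; a stage whose output file already exists is
skipped unless `force` is set.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import clone_typing, composition, delimit, folding, motifs, phylogeny
from . import pseudogene, seqio, tables
from .align import progressive_align
from .trees import write_newick

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta: str
    outdir: str
    seed: int = 0
    reference_fasta: str | None = None  # defaults to the packaged reference
    reference_regions: str | None = None
    identity_floor: float = delimit.DEFAULT_IDENTITY_FLOOR
    bootstrap: int = 100
    model: str = "jc"
    min_type_identity: float = clone_typing.DEFAULT_MIN_TYPE_IDENTITY
    clones_fasta: str | None = None
    accession: str = "accession"
    refs_fasta: str | None = None  # labeled references for genome assignment
    refs_labels: str | None = None  # TSV: id<TAB>genome

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)

    def record_stage(self, name: str, inputs: list[str], outputs: list[str]) -> None:
        self.stages[name] = {
            "inputs": {os.path.basename(p): _sha256(p) for p in inputs},
            "outputs": {os.path.basename(p): _sha256(p) for p in outputs},
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "seed": self.seed,
                       "stages": self.stages}, fh, indent=2)
            fh.write("\n")


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_reference(cfg: PipelineConfig) -> delimit.AnnotatedReference:
    if cfg.reference_fasta is None:
        return delimit.default_reference()
    records = seqio.read_fasta(cfg.reference_fasta)
    regions = tables.read_regions(cfg.reference_regions)
    rec = records[0]
    return delimit.AnnotatedReference(record=rec, annotation=regions[rec.id])


def run_pipeline(cfg: PipelineConfig, force: bool = False) -> RunManifest:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if not os.path.exists(cfg.fasta):
        raise FileNotFoundError(f"input FASTA not found: {cfg.fasta}")
    records = seqio.read_fasta(cfg.fasta)
    if not records:
        raise ValueError(f"no records in {cfg.fasta}")
    manifest = RunManifest(config=cfg.__dict__.copy(), seed=cfg.seed)
    ref = _load_reference(cfg)

    def fresh(path: Path) -> bool:
        return not force and path.exists()

    # -- delimit ----------------------------------------------------------
    regions_tsv = out / "regions.tsv"
    if not fresh(regions_tsv):
        rows = []
        for rec in records:
            try:
                res = delimit.delimit(rec, ref, cfg.identity_floor)
            except delimit.DelimitationError as exc:
                raise StageError("delimit", f"record {rec.id!r}: {exc}") from exc
            rows.append((rec.id, res.annotation, res.score))
        tables.write_regions(regions_tsv, rows)
    manifest.record_stage("delimit", [cfg.fasta], [str(regions_tsv)])
    annotations = tables.read_regions(regions_tsv)

    # -- stats ------------------------------------------------------------
    comp_tsv = out / "composition.tsv"
    pi_tsv = out / "pi.tsv"
    matrix_tsv = out / "identity.tsv"
    msa = None
    if not fresh(comp_tsv):
        reports = [
            composition.composition_report(rec, annotations[rec.id])
            for rec in records
        ]
        tables.write_composition(comp_tsv, reports)
    if len(records) >= 2 and not fresh(pi_tsv):
        msa = progressive_align(records)
        tables.write_identity_matrix(matrix_tsv, composition.identity_matrix(msa))
        tables.write_diversity(pi_tsv, composition.nucleotide_diversity(msa))
    manifest.record_stage("stats", [cfg.fasta, str(regions_tsv)],
                          [str(p) for p in (comp_tsv, matrix_tsv, pi_tsv) if p.exists()])

    # -- motifs -----------------------------------------------------------
    motifs_tsv = out / "motifs.tsv"
    if not fresh(motifs_tsv):
        rows = []
        for rec in records:
            r58s = rec.subregion(*annotations[rec.id].r58s)
            for rep in motifs.scan_all(r58s).values():
                rows.append((rec.id, rep))
        tables.write_motifs(motifs_tsv, rows)
    manifest.record_stage("motifs", [cfg.fasta, str(regions_tsv)], [str(motifs_tsv)])

    # -- fold -------------------------------------------------------------
    structure_tsv = out / "structure.tsv"
    if not fresh(structure_tsv):
        rows = []
        for rec in records:
            ann = annotations[rec.id]
            rows.append((rec.id, folding.structure_report(
                rec.subregion(*ann.its2), rec.subregion(*ann.r58s))))
        tables.write_structure(structure_tsv, rows)
    manifest.record_stage("fold", [cfg.fasta, str(regions_tsv)], [str(structure_tsv)])

    # -- classify ---------------------------------------------------------
    verdicts_tsv = out / "verdicts.tsv"
    if not fresh(verdicts_tsv):
        comps = {c.record_id: c for c in tables.read_composition(comp_tsv)}
        motif_map = tables.read_motifs(motifs_tsv)
        struct_map = tables.read_structure(structure_tsv)
        # cohort: records with intact motifs and structure
        cohort = [
            comps[rid] for rid in comps
            if all(m.n_mismatches == 0 for m in motif_map[rid].values())
            and struct_map[rid].overall_its2_ok and struct_map[rid].overall_58s_ok
        ]
        verdicts = []
        for rec in records:
            verdicts.append(pseudogene.classify(
                comps[rec.id], motif_map[rec.id], struct_map[rec.id],
                cohort=cohort, use_gc_rule=bool(cohort),
            ))
        tables.write_verdicts(verdicts_tsv, verdicts)
    manifest.record_stage(
        "classify", [str(comp_tsv), str(motifs_tsv), str(structure_tsv)],
        [str(verdicts_tsv)],
    )

    # -- type (optional clone library) ------------------------------------
    types_fa = out / "types.fasta"
    if cfg.clones_fasta and not fresh(types_fa):
        clones = seqio.read_fasta(cfg.clones_fasta, source="clone")
        tset = clone_typing.type_clones(
            clones, accession=cfg.accession,
            min_type_identity=cfg.min_type_identity,
        )
        seqio.write_fasta([t.consensus for t in tset.types], types_fa)
        tables._write_tsv(out / "types.tsv", ["type", "support", "members"], [
            [t.consensus.id, t.support, ",".join(t.members)] for t in tset.types
        ])
    if cfg.clones_fasta:
        manifest.record_stage("type", [cfg.clones_fasta],
                              [str(types_fa), str(out / "types.tsv")])

    # -- tree -------------------------------------------------------------
    tree_nwk = out / "tree.nwk"
    if len(records) >= 4 and not fresh(tree_nwk):
        if msa is None:
            msa = progressive_align(records)
        tree = phylogeny.bootstrap_support(
            msa, n_replicates=cfg.bootstrap, seed=cfg.seed, model=cfg.model,
        )
        tree = phylogeny.midpoint_root(tree)
        write_newick(tree, str(tree_nwk))
        manifest.record_stage("tree", [cfg.fasta], [str(tree_nwk)])

    # -- assign (optional) ------------------------------------------------
    assignments_tsv = out / "assignments.tsv"
    if cfg.refs_fasta and cfg.refs_labels and not fresh(assignments_tsv):
        refs = seqio.read_fasta(cfg.refs_fasta)
        labels = {
            row["id"]: row["genome"]
            for row in tables._read_tsv(cfg.refs_labels)
        }
        rmsa = progressive_align(refs)
        queries = (
            seqio.read_fasta(types_fa, source="consensus")
            if types_fa.exists() else records
        )
        assignments = phylogeny.assign_genome(queries, rmsa, labels)
        tables.write_assignments(assignments_tsv, assignments)
        manifest.record_stage("assign", [cfg.refs_fasta, cfg.refs_labels],
                              [str(assignments_tsv)])

    manifest.write(str(out / "manifest.json"))
    return manifest
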