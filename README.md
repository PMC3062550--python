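# its-profiler

Toolkit for profiling the nuclear ribosomal ITS1–5.8S–ITS2 region:

- **Delimitation** — locate ITS1 / 5.8S / ITS2 boundaries by global alignment
  to an annotated reference (a packaged synthetic reference with known
  boundaries ships with the library).
- **Composition** — per-region lengths, GC content, pairwise identity
  matrices and nucleotide diversity (π) with pairwise deletion.
- **Motif screening** — position-level mismatch calls against the three
  conserved angiosperm 5.8S motifs (M1 16 nt, M2 14 nt, M3 10 nt).
- **Structure screening** — ITS2 four-helix topology checks (TGGT in helix
  III, pyrimidine–pyrimidine internal loop in helix II) via deterministic
  maximum-base-pairing folding, plus satisfiability of the six fixed 5.8S
  helix pairing constraints (B4–B8b).
- **Pseudogene classification** — combines motif, structure and
  cohort-relative GC/length evidence into
  functional / suspect / putative_pseudogene verdicts.
- **Clone typing** — collapses clone libraries (progressive MSA,
  single-linkage clustering, majority consensus) into distinct ITS types.
- **Phylogenetics** — p / Jukes–Cantor distances, neighbor joining with
  nonparametric bootstrap, midpoint rooting, Newick I/O.
- **Genome assignment** — assigns hybrid ITS types to parental genome groups
  (A/B/S/T/…) by mean JC distance to labeled references.
- **Read depth** — local-alignment read placement and per-position coverage
  profiles along an ITS contig.
- **Synthetic data** — a fully seeded generator producing functional
  templates (motifs and pairing constraints satisfied by construction),
  pseudogenized derivatives (CpG deamination, targeted motif hits, helix
  breaks, a 41-nt ITS1 deletion), clone libraries, hybrid type sets and
  shotgun reads — so the whole pipeline is testable offline.

## CLI

All stages are subcommands of `its-profiler` (run any with `--help`):

```bash
# generate a demo fixture set (templates, a pseudogene, clones, reads)
its-profiler simulate --seed 1 --outdir fixtures/

# full pipeline with a run manifest
its-profiler run --fasta fixtures/sequences.fasta --outdir out/ --seed 1

# or stage by stage
its-profiler delimit  --fasta in.fa --out regions.tsv
its-profiler stats    --fasta in.fa --regions regions.tsv --out composition.tsv \
                      --matrix identity.tsv --pi pi.tsv
its-profiler motifs   --fasta in.fa --regions regions.tsv --out motifs.tsv
its-profiler fold     --fasta in.fa --regions regions.tsv --out structure.tsv
its-profiler classify --composition composition.tsv --motifs motifs.tsv \
                      --structure structure.tsv --out verdicts.tsv
its-profiler type     --fasta clones.fa --accession ITC0539 --out types.fa \
                      --report types.tsv
its-profiler tree     --msa aln.fa --model jc --bootstrap 1000 --seed 42 \
                      --out tree.nwk
its-profiler assign   --queries types.fa --refs refs.fa --labels labels.tsv \
                      --out assignments.tsv
its-profiler rd       --reads reads.fa --contig contig.fa --out rd.tsv
```

`delimit` defaults to the packaged synthetic reference; pass `--reference`
plus `--annotation` (a regions TSV) to use your own. Every subcommand logs
its parameters and seed; pipeline runs write `manifest.json` with
input/output SHA-256 hashes so deterministic stages can be verified to
reproduce bit-identical results.

## Conventions

- Coordinates are 1-based inclusive throughout.
- Sequences are normalized on input: upper-case, U→T, ambiguity codes other
  than N collapsed to N. N never counts as a match, a GC base, or a
  pairable base.
- Percent identity excludes gap–gap and N columns and counts gap-vs-base as
  a mismatch; π uses pairwise deletion.
- Folding is maximum-cardinality nested pairing (AT/GC/GT, minimum hairpin
  loop 3) with a span-minimizing tiebreak — a deterministic topological
  stand-in for thermodynamic folding, not an energy model.
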