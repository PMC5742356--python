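# scfvtools

Analysis pipeline for full-length single-chain Fv (scFv) long-read amplicon
data: detection and germline annotation of the two V domains carried by each
read, dual-domain quality filtering with per-batch coverage summaries,
VH–VL clonotype association ranking, and replicate-aware tracking of a
reference clone with mutation nomenclature, localization on the amplicon
geometry, and provenance classification (library variant vs putative
artifact).

A synthetic library module simulates the full amplicon structure — forward /
reverse primers, phagemid vector flanks, a 53-nt linker with EcoRI/XbaI
sites, recombined V-(D)-J domains with N-diversity and per-domain mutation
rates, clone-abundance enrichment, and a residual consensus error model with
primer-end deletion artifacts — with complete per-read ground truth, so the
whole pipeline is testable without external data.

## Layout

| module | purpose |
| --- | --- |
| `scfvtools.germline` | germline V/(D)/J reference directories (FASTA + TSV sidecar), built-in fixture set |
| `scfvtools.simulate` | library / clone / read simulator with truth records |
| `scfvtools.annotate` | dual V-domain detection, germline assignment, junctions, layout, linker |
| `scfvtools.filtering` | >85%-identity + in-frame filter, batch summaries, layout tallies |
| `scfvtools.tracking` | clonotype keys, association ranking, reference-clone tracking, identity classes, mutation provenance |
| `scfvtools.fixture` | deterministic 85-read tracking reconstruction (53 / 7 / 25 reads) |
| `scfvtools.cli` | `simulate`, `analyze`, `track`, `fixture` subcommands |

## CLI

```bash
# simulate a library and reads (FASTQ + truth + geometry + germline set)
scfvtools simulate --seed 7 --n-reads 5000 --out out/sim

# annotate, filter, summarize, and rank clonotype associations
scfvtools analyze --reads out/sim/reads.fastq --fixture-reference-seed 7 \
    --read-meta out/sim/read_meta.tsv --out out/ana

# emit the 85-read tracking reconstruction and track the reference clone
scfvtools fixture --seed 0 --out out/fx
scfvtools track --reads out/fx/reads.fasta --read-meta out/fx/read_meta.tsv \
    --reference-insert out/fx/reference_insert.fasta \
    --geometry out/fx/geometry.json --out out/trk
```

All tables are TSV with a header comment recording the tool version, a
config hash, and the seed; reruns on identical inputs are byte-identical.

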