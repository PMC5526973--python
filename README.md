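# phyloscreen

A pipeline for screening genes differentially regulated under a focal
condition relative to multiple comparison conditions, built around
small-sample statistics: unidirectional entry screening with a
mean-vs-mean fold threshold, a heteroscedastic effect-size correlation
*r* for unequal group sizes, noncentral-t post-hoc power, Benjamini-
Hochberg FDR, comparative-Ct (2^−ΔΔCt) qPCR quantification, exact IUPAC
promoter-motif scanning with background-normalized read coverage, scored
PPI-network statistics, GO hypergeometric enrichment (with a
conservative doubled-FDR adjustment), and dN/dS rate comparisons.
A synthetic-data module generates every input format with planted,
serialized ground truth so the whole pipeline is testable offline.

## Layout

| module | contents |
| --- | --- |
| `phyloscreen.group_stats` | t-tests, BH FDR, effect-size r, post-hoc power, min fold-change, Mann-Whitney U |
| `phyloscreen.qpcr_quant` | technical-replicate collapsing, 2^−ΔΔCt relative expression |
| `phyloscreen.target_screen` | entry screen, fold filter, classification, validation, reduced-sample re-analysis, dN/dS comparison |
| `phyloscreen.promoter_scan` | promoter extraction, exact IUPAC motif scanning, coverage tracks, co-occurrence reports |
| `phyloscreen.network_go` | threshold views, LCC/degree/clustering statistics, PPI enrichment, GO enrichment |
| `phyloscreen.synthetic_data` | deterministic generators with planted truth for every stage |
| `phyloscreen.io_cli` | TSV/FASTA/BED/bedGraph readers & writers, `PipelineConfig`, pipeline runner, CLI |

## Command line

All stages are exposed through one entry point:

```sh
phyloscreen --config config.yaml --out-dir out simulate --n-genes 200
phyloscreen --config config.yaml --out-dir out screen --expression out/expression.tsv
phyloscreen --config config.yaml --out-dir out qpcr --ct out/ct.tsv
phyloscreen --config config.yaml --out-dir out promoters \
    --genome out/genome.fasta --tss out/tss.bed --motifs out/motifs.tsv \
    --reads out/reads.bed
phyloscreen --config config.yaml --out-dir out network --edges out/edges.tsv
phyloscreen --config config.yaml --out-dir out go \
    --go-annotations out/go_annotations.tsv --sample out/sample.txt \
    --universe out/universe.txt
phyloscreen --config config.yaml --out-dir out dnds --dnds dnds.tsv
```

`all` runs every stage whose inputs are supplied. Global flags:
`--config`, `--seed` (overrides the config seed), `--out-dir`,
`--log-level`. Each run writes a `run.log` recording the config, seed,
and a checksum per input, and identical config + inputs + seed produce
byte-identical result tables.

A minimal config:

```yaml
focal_condition: hsa
comparison_conditions: [ptr, mmu, cja]
control_condition: vector
reference_genes: [GAPDH, RPLP]
seed: 11
```

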