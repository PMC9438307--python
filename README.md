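# olfevo

Olfactory receptor repertoire evolution in fishes, as a tested, reusable
pipeline: mine receptor loci (OR / TAAR / OlfC / ORA) from genome
sequence and classify each as gene / pseudogene / truncated / edge;
reconcile gene trees with a time-calibrated species tree to per-branch
gene gains and losses; convert those to birth and death rates per gene
per million years; and run phylogenetic comparative regressions (PGLS
with ML Pagel's λ) linking repertoire size to olfactory-organ
morphology. Every stage is exercised end to end on synthetic genomes and
simulated gene-family histories with known ground truth.

## Layout

| module | role |
|---|---|
| `olfevo.trees`, `olfevo.io`, `olfevo.config`, `olfevo.cli` | shared types (TimeTree, GeneTree), FASTA/Newick/TSV/config I/O, CLI |
| `olfevo.simulate` | species trees, birth–death family histories (lineage-tracked), reference panels, sequence-level genomes with planted locus states, lamellae traits |
| `olfevo.mining` | six-frame translated Smith–Waterman with Karlin–Altschul E-values, hit-region merging, spliced protein-to-genome alignment (GT..AG introns, frameshifts, stop readthrough), four-way status classification, BLASTX-style family assignment with decoys, dedup |
| `olfevo.reconcile` | support-based collapse, LCA duplication–loss reconciliation with per-branch loss placement, exhaustive rooting/resolution search, branch-event tables |
| `olfevo.rates` | per-branch and gene-time-pooled birth/death rates with short-branch exclusion |
| `olfevo.comparative` | PGLS with ML λ, phylogenetic-signal tests, per-branch Pearson correlations |

## CLI

All subcommands log their configuration and seed and write a
`config.txt` alongside their outputs; reruns with the same seed are
byte-identical.

```sh
olfevo simulate --seed 1 --taxa 8 --crown-age 150 --out-dir run/
olfevo mine --genome run/genome_sp1.fasta --panel run/panel.fasta --out-dir run/mine_sp1/
olfevo classify-trees --trees genes.nwk --support-collapse 90 --out collapsed.nwk
olfevo reconcile --species-tree run/species_tree.nwk --gene-trees genes.nwk --out events.tsv
olfevo rates --events events.tsv --min-branch-my 2 --out-dir run/rates/
olfevo pgls --traits run/traits.tsv --tree run/species_tree.nwk --response lamellae --predictor OR
olfevo report --traits run/traits.tsv --tree run/species_tree.nwk --out report.tsv
```

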