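# comotif

Screening TF ChIP-seq peak compendia for cell-type-specific and TF-specific
transcriptional **cofactor binding-site motifs**.

Given per-experiment peak intervals (BED), a genome (FASTA), experiment
metadata, a motif library (JASPAR / UniPROBE dialects) and a target-TF →
canonical-motif map, the pipeline:

1. **curates** the compendium — drops general-machinery/CTCF targets, orphan
   experiments (TF assayed in one cell type) and TFs without a canonical
   motif, then removes peaks in HOT regions (bases covered by peaks from
   strictly more than 50% of experiments, found by a sweep line);
2. **scans** every COLD peak with every library motif using integer-scaled
   log-odds matrices and **exact p-values** from the PWM score distribution
   (dynamic programming over columns, both strands, per-experiment 0-order
   background); a peak "contains" a motif when its best hit has p ≤ 1e-4;
3. **partitions** each experiment's peaks into canonical-motif-positive and
   -negative sets and tabulates per-(experiment, motif, class) abundances,
   where class is *proximal* (positive peaks) or *distal* (negative peaks);
4. **screens**: flags within-experiment enrichment above the 95th-percentile
   abundance, removes ubiquitous motifs (flag fraction ≥ 20% proximal / ≥ 10%
   distal across experiments), then calls cell-type-specific motifs
   (≥ 10 experiments of one cell type spanning ≥ 4 TFs, abundance > 15%) and
   TF-specific motifs (≥ 3 sister cell types, abundance > 20% in all);
5. **removes similarity false positives**: candidate cofactors whose
   ungapped-alignment empirical p-value against the target TF's canonical
   motif(s) is below 0.05 (Pearson column correlation, column-shuffle null).

A seeded synthetic-compendium generator plants canonical and cofactor motifs
under controllable scenarios (cell-type-specific, TF-specific, ubiquitous,
canonical-decoy, HOT-only) and emits a truth table, so the whole screen is
testable end to end with known ground truth.

## CLI

```sh
# generate the default planted-truth compendium (73 screenable experiments)
comotif simulate --out sim --seed 42

# run the screen
comotif screen --genome sim/genome.fa --peaks-dir sim/peaks \
    --metadata sim/metadata.tsv --motifs sim/motifs.jaspar \
    --canonical-map sim/canonical_map.tsv --out out --seed 42

# compare calls against the planted truth
comotif evaluate --calls-dir out --truth sim/truth.csv

# summarize a finished run from cached stage artifacts
comotif report --out out
```

`comotif screen` also accepts `--config cfg.yaml` (flags override fields) and
`--stages curation` to stop after curation. Outputs in `--out`:
`curation_report.tsv`, `hot_regions.bed`, `abundance_records.tsv`,
`proximal.csv`, `distal.csv`, `cell_type_specific.csv`, `tf_specific.csv`,
`summary.csv`, and `run_manifest.json`. All screening thresholds live in one
`ScreenThresholds` block and can be overridden via the YAML config.

## Layout

| module | contents |
| --- | --- |
| `comotif.motifs` | PWM/Background/LogOddsMatrix, JASPAR & UniPROBE parsers, serialization |
| `comotif.scan` | exact score distributions, scanning, BH q-values, presence calls |
| `comotif.similarity` | ungapped alignment, column-shuffle p-values, false-positive rule |
| `comotif.curation` | metadata/BED/FASTA loading, experiment filters, HOT regions |
| `comotif.screen` | partitioning, abundances, enrichment flags, specificity screens, reports |
| `comotif.simulate` | synthetic compendium generator + truth table + evaluation |
| `comotif.pipeline` / `comotif.cli` | orchestration, YAML config, click CLI |
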