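# bomscope

Feature discovery for bone-metastasis (BoM) tumor microenvironments from
bulk and single-cell RNA counts. The package implements, as a tested and
reusable pipeline:

- **`bulk_de`** — in-house negative-binomial Wald differential expression
  (median-of-ratios size factors, method-of-moments dispersion, BH
  adjustment) and the two-comparison overlap rule that yields a BoM gene
  panel (up in Meta-vs-nonMeta *and* up in BoM-vs-nonBoM).
- **`sc_core`** — single-cell I/O (MTX triplet / TSV), log-normalization,
  dot-profile statistics (z-scored subgroup means + positive-expression
  ratios), one-vs-rest Wilcoxon marker detection, panel–marker overlap.
- **`bom_screen`** — condition-stratified upregulation screens: per-subgroup
  BoM-vs-Other rank-sum tests with the >10%-expressing pre-filter, and
  multi-level pairwise sample-type comparisons with Bonferroni stars. Also
  home of the rank-sum primitive (exact enumeration for small untied
  samples, tie/continuity-corrected normal approximation otherwise).
- **`lr_screen`** — the 5-step ligand–receptor candidate screen between two
  subgroups against a cellphoneDB-style pair table (simple gene–gene rows;
  complexes must be pre-expanded).
- **`correlate`** — Pearson correlation validation within subgroups (with
  the R > 0.2 high-correlation rule) and a per-cancer-type bulk mode.
- **`enrich`** — hypergeometric over-representation against GMT gene sets.
- **`synthetic_data`** — planted-truth simulators for bulk counts,
  single-cell counts (markers, condition effects, co-expressed
  ligand–receptor programs) and L-R databases with decoys, so every screen
  has a ground-truth test surface.
- **`pipeline`** — YAML-configured orchestration of the full flow with a
  machine-readable manifest; byte-identical reruns under a fixed seed.

## CLI

Every stage is exposed under a single entry point:

```sh
# synthetic fixtures (bulk counts, single-cell counts, L-R database)
bomscope simulate bulk --seed 42 --out data/bulk
bomscope simulate sc   --seed 42 --out data/sc
bomscope simulate lrdb --seed 42 --out data

# stage-by-stage
bomscope bulk-de --counts data/bulk/bulk_counts.tsv --samples data/bulk/bulk_samples.tsv \
    --group-col meta_status --reference nonMeta --treatment Meta --out de_meta.tsv
bomscope panel --de-meta de_meta.tsv --de-bom de_bom.tsv --out panel.tsv
bomscope markers --counts data/sc --cells data/sc/cells.tsv --out markers.tsv
bomscope bom-screen --counts data/sc --cells data/sc/cells.tsv --subgroup fibroblast --out screen.tsv
bomscope lr-screen --counts data/sc --cells data/sc/cells.tsv --db data/lr_db.csv \
    --from fibroblast --to tumor1 --out candidates.tsv
bomscope correlate sc --counts data/sc --cells data/sc/cells.tsv --subgroup fibroblast \
    --anchors G0101 --targets G0121,G0122 --out corr.tsv
bomscope enrich --query @genes.txt --gmt sets.gmt --out enrichment.tsv

# everything from one YAML config
bomscope run-all --config config.yaml
```

`run-all` reads a YAML file with paths (`bulk_counts`, `bulk_samples`,
`sc_counts`, `sc_cells`, `lr_db`, optional `gmt`, `out_dir`), thresholds
(`alpha`, `min_ratio`, `high_corr_threshold`, `adjustment`), the subgroups
to screen (`screen_subgroups`, `lr_pairs`), correlation gene lists
(`corr_subgroup`, `corr_anchors`, `corr_targets`) and a `seed`. Exit codes:
0 success, 2 validation failure, 1 runtime failure.

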