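# halotrait

Eco-evolutionary trait analysis of soil microbial taxa along a salinity
(electrical conductivity, EC) gradient. Starting from annotated abundance
tables, the pipeline

- classifies taxa into four salinity-response groups (pos/neg × bacteria/
  archaea): `<100`-total-abundance filter, per-taxon OLS of abundance on EC,
  sign/significance classification at p < 0.05, top-200 bacteria / top-50
  archaea per direction by total abundance, and validation against published
  salt-tolerant genus prefixes;
- detects response breakpoints with continuous two-segment least squares
  (profiled-RSS grid search + golden-section refinement) and a linear-vs-
  segmented F-test/BIC model choice;
- normalizes per-taxon functional-gene content (NACG = category gene
  abundance / taxon abundance), aggregates it over KEGG BRITE level-1/3
  pathway labels, and computes C-acquisition investment fractions and KO
  alpha diversity;
- scores mechanism completeness (3 salt-resistance, 7 C-fixation, 6 CAZyme
  classes) with UpSet-style exact-subset counts;
- runs group contrasts (Mann–Whitney U: exact by enumeration for small
  untied samples, tie-corrected normal approximation otherwise), genome-size
  comparisons (between groups, within a shared phylum, vs reference phylum
  distributions), partial correlation controlling for EC, the
  `p < 0.05 ∧ |Δmean| > 0.001` biomarker-pathway rule, and average-linkage
  clustering;
- ranks level-3 pathways against EC with iterated random forests and selects
  a biomarker count by 10-fold cross-validation (1-SE rule).

A synthetic-data module generates full datasets with planted ground truth
(response classes, breakpoints, gene copy numbers, mechanism presence sets,
clade-structured genome sizes), so every stage is testable offline. With all
noise disabled the generator is exact and recovery checks assert equality.

## CLI

```sh
# generate a synthetic dataset (+ ground_truth*.tsv) into data/
halotrait simulate --config config.yaml --out data --seed 1

# run every stage; outputs are TSV/JSON in out/
halotrait run --config config.yaml --data data --out out --seed 1

# individual stages
halotrait classify   --data data --out out
halotrait segfit     --data data --out out [--per-taxon]
halotrait traits     --data data --out out
halotrait mechanisms --data data --out out
halotrait contrasts  --data data --out out
halotrait rf-select  --data data --out out --seed 1
```

The YAML config has two optional sections, `synth` (fields of
`halotrait.synth.SynthConfig`) and `pipeline` (fields of
`halotrait.pipeline.PipelineConfig`), e.g.

```yaml
synth:
  n_samples: 37
  ec_range: [0.14, 13.65]
  nb_dispersion: 15.0
pipeline:
  n_bac: 200
  n_arch: 50
  rf_trees: 100       # raise to 1000 for full-scale runs
  rf_iterations: 20   # raise to 100 for full-scale runs
```

## Dataset layout

A dataset directory holds six plain-text files: `samples.tsv`
(sample_id, ec, covariates…), `taxa.tsv` (taxon_id, domain, phylum, genus,
genome_size_mb), `abundance.tsv` (taxon × sample matrix),
`gene_abundance.tsv` (long-format taxon_id, gene_id, sample_id, abundance),
`catalog.json` (gene → BRITE level-1/2/3 pathway map + mechanism
definitions), `references.json` (salt-tolerant genus prefixes, reference
genome-size distributions). A placeholder default catalog ships in
`halotrait.core.default_catalog()`; substitute your own `catalog.json` for
real KO/CAZyme lists. Taxon abundances are treated as opaque non-negative
values (no transformation is applied before regression by default; a
`log1p` switch exists).

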