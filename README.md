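# spikequant

A tested pipeline for spike-in DIA absolute quantification of plasma
proteins, built around five analysis stages plus a ground-truthed synthetic
cohort generator so every stage is verifiable without raw instrument data:

- **`spikequant.synthetic`** — generates a full synthetic study: a 96-well
  plate manifest with pooled-plasma triplicates per plate, true protein
  concentrations spanning a configurable dynamic range with planted disease
  and sex effects, a spike-in panel, and a transition-level report with
  three-level lognormal noise, missingness, corrupted library scores and
  designed QC-failing samples.
- **`spikequant.formats_io`** — strict CSV readers/writers for all tables
  (a mapping layer loads genuine Skyline transition exports via
  `dialect="skyline"`).
- **`spikequant.quantify`** — the quantification core: light/heavy
  transition pairing, summed-area ratio to standard, recomputed ratio dot
  product, score/ratio filtering (rdotp > 0.7, dotp > 0.5,
  0.01 < r < 1000, all strict), anchor-peptide RT~iRT sample QC with a
  minimum-quantified-proteins gate, conversion to pmol/µL via the spiked
  amounts, a 50% quantification-rate filter, pool-based per-peptide
  per-plate median normalization, and median roll-up to proteins.
- **`spikequant.qc_metrics`** — intra-assay CV of pool replicates (per
  plate and across all plates), pairwise pool Pearson correlation on log10
  concentrations, and the normalized IQR (Q3/Q1 by default,
  (Q3−Q1)/median behind a flag).
- **`spikequant.diffexp`** — one-vs-rest differential abundance per cancer
  on log2 peptide concentrations (Welch t by default, pooled optional),
  sex-restricted comparisons for sex-specific cancers, Bonferroni
  adjustment within each comparison, volcano and network-edge tables.
- **`spikequant.classify`** — kNN imputation (leakage-safe by default,
  impute-first mode available), stratified 70/30 split, 5-fold
  cross-validated random forest, holdout ROC/AUC with a Mann–Whitney
  oracle check, and 0–100 feature relevance scores.

## CLI

```sh
# generate a desk-scale synthetic study (~350 patients, 4 plates)
spikequant simulate --out out/ --seed 1

# quantify a transition report
spikequant quantify --report out/transition_report.csv \
    --panel out/panel.csv --manifest out/manifest.csv \
    --out out/ --min-proteins 30

# QC, differential abundance, classification
spikequant qc --peptides out/peptide_concentrations.csv \
    --proteins out/protein_concentrations.csv \
    --manifest out/manifest.csv --out out/qc_report.json
spikequant diffexp --peptides out/peptide_concentrations.csv \
    --manifest out/manifest.csv --out out/ --alpha 0.0005
spikequant classify --peptides out/peptide_concentrations.csv \
    --manifest out/manifest.csv --out out/ --seed 1

# or everything at once (accepts a flat YAML config of overrides)
spikequant run-all --out out/ --seed 1
```

Every stage writes a JSON provenance block (input counts, records dropped
per filter with reasons, thresholds, seeds). Outputs are deterministic
functions of (inputs, config, seed); re-running with the same seed gives
byte-identical tables.

## Layout

```
src/spikequant/    package modules (one per pipeline stage)
tests/             pytest suite; tests/test_acceptance.py holds the
                   end-to-end acceptance criteria
scripts/           acceptance report script
```
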