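# mwaskit

An untargeted LC-HRMS metabolome-wide association pipeline for
dual-column (HILIC+ESI+ / C18+ESI−) feature tables, built around a
newborn dried-blood-spot smoking-exposure study design:

1. **synthetic** — seeded generator for dual-mode feature tables
   (triplicate injections, batches of ≤ 40 samples, intensity-dependent
   missingness, realistic replicate CVs), covariate tables, a pathway
   database, planted exposure effects and a planted enriched pathway.
2. **qc** — feature filters (< 30% missing at the summarized-sample
   level, median replicate CV < 30%, median replicate Pearson > 0.7),
   median replicate summarization, log2, per-batch median centering,
   auto-scaling, kNN imputation (k = 10).
3. **exposure** — cotinine (m/z 177.1023) / hydroxycotinine
   (m/z 193.0973) extraction at 5 ppm, the union classification rule
   (reported smoker OR cotinine detected OR hydroxycotinine in the top
   14%), and cohort summary bookkeeping.
4. **adjust** — OLS residualization of every feature against maternal
   race/ethnicity, maternal age band, birth-year band, infant sex and
   SES quintile (biomarkers passed through untouched).
5. **plsda** — NIPALS PLS1 against the centered class indicator, VIP
   scores (Σ VIP² = n features), selection at VIP ≥ 2, fold changes,
   score-plot export with 95% confidence ellipses.
6. **association** — per-feature univariate logistic regression (IRLS),
   Wald p-values, Benjamini–Hochberg FDR per mode, type-2
   Manhattan-table export (top-20 labels, p < 0.001 highlighting).
7. **annotate** — level-1 matching against an authentic-standard
   library (±5 ppm, ±15 s) and level-4 formula/mass annotation over the
   mode's adduct list (10 ppm) with an adduct-support confidence count.
8. **pathway** — mummichog-style enrichment: m/z → metabolite mapping
   through adduct masses, EASE score (hypergeometric tail after removing
   one hit), resampling null, gamma-CDF adjusted p-values, overlap ≥ 3
   reporting, significance at gamma-adjusted p < 0.05.

## CLI

```bash
mwaskit simulate --seed 1 --outdir run/           # synthetic study
mwaskit run-all  --seed 1 --outdir run/           # every stage + manifest.json
mwaskit qc --features run/features_hilic_pos.tsv \
           --batches run/batches_hilic_pos.tsv --mode hilic_pos --outdir run/
mwaskit classify --features ... --batches ... --samples run/samples.tsv --outdir run/
mwaskit adjust --matrix run/processed_hilic_pos.tsv --samples run/samples.tsv --out run/adjusted.tsv
mwaskit plsda --matrix run/adjusted.tsv --calls run/exposure_calls.tsv --outdir run/
mwaskit associate --matrix run/adjusted.tsv --calls run/exposure_calls.tsv \
                  --selection run/selection.tsv --out run/associations.tsv
mwaskit annotate --features feats.tsv --mode hilic_pos --out hits.tsv
mwaskit enrich --selection sel.tsv --pathways run/pathways.json --mode hilic_pos --out enr.tsv
```

`--config config.json` supplies generator/pipeline settings; CLI flags
override it. Outputs are plain TSV/JSON throughout; missing intensities
are empty cells (never 0).

## Data formats

* **Feature table** (TSV): columns `mz`, `time`, then one column per
  injection named `<sample>.<replicate>` (three replicates per sample);
  a companion batch map TSV has columns `injection_id`, `batch`.
* **Covariates** (TSV): `sample_id`, `reported_smoker`,
  `race_ethnicity`, `maternal_age`, `birth_year_band`, `sex`, `ses`.
* **Reference library / pathway database**: JSON (see
  `src/mwaskit/data/reference_library.json` for the bundled
  authentic-standard mini-library).

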