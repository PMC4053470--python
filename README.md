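# genometab

Joint genomic–metabolomic analysis of urinary albumin excretion (UAE) in a
general-population cohort, packaged as a tested, reusable pipeline:

- **`genometab.simulate`** — synthetic cohorts: clinical covariates, genotypes
  in Hardy–Weinberg proportions, a log10 ACR generative model calibrated to a
  target microalbuminuria prevalence (ACR ≥ 30 µg/mg), group-conditional
  metabolite levels, and forward-modelled 1H-NMR spectra built from Lorentzian
  peaks whose window integrals reproduce the levels exactly.
- **`genometab.spectra`** — spectrum preprocessing: referencing to the alanine
  doublet at 1.478 ppm, 0.01-ppm binning over 0.50–4.70 ppm, total-aliphatic-
  area normalization, reduction to a packaged set of 51 analysis regions, and
  quantification of 26 named metabolite windows (percent of total area).
- **`genometab.chemometrics`** — PCA and from-scratch NIPALS PLS-DA with
  10×10 venetian-blind cross-validation, Q2 (averaged label/prediction
  correlation, plus 1−PRESS/TSS as `q2_press`), RMSCV and VIP feature ranking.
- **`genometab.genassoc`** — genotype QC (call rate > 90 %, Hardy–Weinberg χ²
  with 1 df), additive/dominant/recessive association of log10 UAE adjusted
  for age, sex, BMI, SBP and fasting glucose, logistic models for the
  microalbuminuria flag, Holm–Bonferroni correction and post-hoc power.
- **`genometab.integrate`** — genotype-stratified metabolite comparisons:
  significance-category matrices, normalized difference ratios (stratum
  difference ÷ cohort difference), per-stratum PLS-DA, discordant-genotype
  selection, and clinical subgroup characterization.
- **`genometab.pipeline` / CLI** — end-to-end orchestration with YAML config,
  deterministic from a single master seed.

No external data are required: the simulate module generates cohorts with the
published statistical structure.

## CLI

```sh
genometab simulate --n 1231 --seed 7 --out cohort/
genometab process-spectra --manifest cohort/spectra/manifest.csv --out feats/
genometab plsda --features feats/metabolite_levels.csv --pheno cohort/phenotypes.csv --label malb
genometab associate --geno cohort/genotypes.tsv --pheno cohort/phenotypes.csv
genometab integrate --features feats/metabolite_levels.csv --pheno cohort/phenotypes.csv \
    --geno cohort/genotypes.tsv --out integ/
genometab run --out results/ --seed 1          # full pipeline, default config
genometab run --config my_config.yaml          # everything configurable
```

Genotypes are read either as a simple TSV (rows = subjects, columns = SNPs,
values `AA`/`AB`/`BB`/`NA`) or as PLINK-style `.ped`/`.map` text.

## Layout

```
src/genometab/
  simulate/        generators + parameter specs (defaults in data/*.tsv)
  spectra.py       preprocessing & quantification
  chemometrics.py  PCA / PLS-DA / CV / VIP
  genassoc.py      QC, association, Holm, power
  integrate.py     stratified differences & discordance selection
  io.py, config.py, pipeline.py, cli.py
  data/            metabolite windows, analysis regions, SNP panel
tests/             unit, property (hypothesis) and acceptance suites
scripts/acceptance.py
```
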