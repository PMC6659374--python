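# urinmr

Quantitative urine ¹H-NMR metabolomics toolkit:

- **`urinmr.signatures_io`** — domain types (spectra on a decreasing ppm axis,
  metabolite signatures built from proton groups and J-couplings,
  concentration tables with unit state, cohort designs) and readers/writers
  for two-column spectrum text, simple JCAMP-DX, TSV signature libraries and
  tables.
- **`urinmr.synthspec`** — synthetic urine spectrum and cohort generator:
  Lorentzian multiplets from coupling trees, TSP reference singlet,
  per-sample chemical-shift jitter, smooth random baseline,
  water-suppression dead zone, additive noise; log-normal
  inter-/intra-individual concentration layers calibrated by CV%, replicate
  series, and a Hardy–Weinberg dosage simulator.
- **`urinmr.ctlsfit`** — constrained total line-shape fitting: per-window
  bound-constrained nonlinear least squares where multiplet positions and
  intensity ratios are fixed by molecular prior knowledge, with residual-peak
  detection of unidentified signals and TSP-referenced conversion of areas
  to absolute concentrations.
- **`urinmr.autoquant`** — fully automated quantification: ridge regression
  from binned spectral intensities to line-shape-fit signal areas, spectrum
  QC (shimming/baseline/reference checks) and Bland-Altman agreement
  reports.
- **`urinmr.quantvar`** — creatinine normalization and the three variability
  layers (intra-assay, intra-individual, inter-individual CV%), plus
  below-detection accounting.
- **`urinmr.epistats`** — log/SD scaling, sex-adjusted partial-correlation
  maps with hierarchical-clustering ordering, PCA-based effective number of
  tests with Bonferroni thresholds, exposure associations in SD units,
  inverse rank-based normal transformation, and an additive dosage
  association scan with MAF/info filters.
- **`urinmr.cli`** — a `urinmr` command that orchestrates
  simulate → QC → fit → normalize → CV → epidemiology as one seeded run.

No external data are required: every analysis is exercisable end-to-end on
the synthetic generator, with the packaged signature library
(`src/urinmr/data/library.tsv`, 19 metabolites), window plan
(`windows.yaml`) and cohort calibration table (`cohort_calibration.tsv`).

## Command line

```bash
# full pipeline demo (50 individuals, seeded, reproducible)
urinmr run --out demo_run --seed 1 --n 50

# stage by stage
urinmr simulate --n 20 --seed 1 --out sim
urinmr fit --spectra sim/spectra --out conc.tsv --log fits.jsonl
urinmr cv --conc conc.tsv --design sim/design.tsv --out cv_report.tsv
urinmr autoquant-train --spectra sim/spectra --labels conc.tsv \
    --metabolite glucose --out model.json
urinmr autoquant-predict --model model.json --spectra sim/spectra --out areas.tsv
urinmr epi corr --conc conc.tsv --covars sim/covariates.tsv --out corr.tsv
urinmr epi meff --conc conc.tsv
```

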