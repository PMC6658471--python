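# polyport

Cross-ancestry polygenic score portability toolkit. Implements, as a tested
reusable pipeline:

1. **Effect-size portability meta-analysis** — within-study normalization of a
   non-European sample's polygenic-score performance to the matched European
   baseline (odds ratios compared on the log scale, ×100 so parity = 100%),
   per-ancestry-group medians, and one-sample t-tests against parity.
2. **Clumping + thresholding (C+T) polygenic scoring** — allele harmonization
   against a target panel, greedy LD clumping against a chosen reference
   population (500 kb window; r² ∈ {0.2, 0.05, 0.01} by default), a 13-level
   p-value-threshold grid, and additive scoring, evaluated as a full factorial
   grid over clump specs × thresholds.
3. **Ancestry structure** — long-range-LD region masks (chr6 25–35 Mb MHC,
   chr8 7–13 Mb inversion), sliding-window LD pruning, genotype PCA
   (Patterson scaling, 20 components), and a PRS-vs-PC correlation scan with
   optional Benjamini–Hochberg adjustment.
4. **Population-level summaries** — per-population score distributions across
   the methods grid, a between-population dispersion statistic, standard
   population exclusion rules, and population-mean-PRS vs population-mean-
   phenotype correlation.
5. **Synthetic data** — Balding–Nichols multi-population genotypes with
   Gaussian-copula LD blocks, additive phenotypes at exact in-sample
   heritability, a marginal-OLS discovery GWAS, controllable
   uncorrected-stratification bias, and study-table / phenotype-table
   fixtures, so the whole pipeline is testable without downloads.

## Layout

```
src/polyport/
  io_formats.py              # VCF / summary stats / panel / table readers+writers
  synthetic_data.py          # simulators and fixtures
  prs_engine.py              # harmonize, clump, threshold, score, score_grid
  ancestry_structure.py      # region masks, LD pruning, PCA, PRS–PC scan
  portability_meta.py        # relative effects, group medians/t-tests
  population_correlation.py  # population summaries, exclusions, correlations
  cli.py                     # polyport meta / demo / score
```

## CLI

```sh
# effect-size meta-analysis of a study-comparison CSV
polyport meta --study-table comparisons.csv --out results/meta

# seeded end-to-end synthetic demo: 3 populations -> discovery GWAS ->
# 3 r² × 3 reference panels × 13 thresholds score grid -> distribution grid,
# PRS–PC scan (unbiased + stratification-biased), population correlation.
# Outputs are byte-stable for a fixed seed.
polyport demo --seed 1 --out results/demo

# real-data adapter: VCF + panel + GWAS summary statistics
polyport score --vcf cohort.vcf --panel samples.panel \
    --sumstats height.txt --reference-populations ALL,EUR,AFR \
    --out results/scores
```

## Conventions

- Coordinates are 1-based, inclusive; all region arithmetic uses closed
  intervals.
- MAF filters are computed on the loaded cohort's non-missing dosages.
- Missing genotypes stay `NaN` until scoring (cohort-mean dosage by default).
- Thresholding is strict (`p < p_T`) except `p_T = 1`, which keeps all rows.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; no global RNG state.
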