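# liverqtl

A toolkit for building a liver eQTL resource from genotype and RNA-Seq
expression data, exercised end-to-end on synthetic cohorts with known
ground truth. It covers:

- **Sample QC** (`liverqtl.sample_qc`) — genotype call-rate exclusion, sex
  concordance from X-chromosome heterozygosity and XIST/RPS4Y1-style
  marker expression, duplicate screening via genotype concordance, and
  genotype/expression **swap detection** by predicting expression of the
  most strongly cis-regulated genes from genotypes.
- **Preprocessing** (`liverqtl.preprocess`) — variant filters (call rate,
  MAF, exact Hardy–Weinberg test), gene expression filters, quantile
  normalization to the average empirical distribution, rank-based inverse
  normal transform, genotype PCs and expression-factor covariates.
- **Association mapping** (`liverqtl.association`) — covariate-adjusted
  linear cis scan (residualization + correlation-to-t identity, verified
  against per-pair OLS to 1e-8), gene-level (eGene) p-values from adaptive
  permutations with Beta-distribution extrapolation, allelic fold-change
  fits under a log-of-linear model, BH FDR, trans scans with greedy
  regional clumping and quality flags (cross-mappability, multi-region,
  missing symbol, pseudogene).
- **Splicing QTLs** (`liverqtl.sqtl`) — exon-usage proportions tested
  with a distance-based pseudo-F statistic and permutation p-values.
- **Enrichment** (`liverqtl.enrichment`) — gene-set log odds ratios from
  logistic regression (optionally adjusted for average expression),
  Wald CIs, and Cochran's Q heterogeneity tests across datasets.
- **Tissue specificity** (`liverqtl.specificity`) — tissue clustering on
  1 − Spearman correlation of eQTL posterior profiles, a rank-based
  liver-specificity score (sum of liver ranks over mean non-liver rank),
  and a rank-sum set-enrichment test.
- **Omnibus TWAS** (`liverqtl.twas`) — a directional combination
  z = Σ zᵢ / √v with v = Σᵢⱼ ρᵢⱼ that corrects for correlation between
  reference panels (estimated across genes), handles per-gene missing
  datasets, rescales so the empirical quartiles match the standard normal
  quartiles, and a calibration simulator contrasting it with the naive
  Stouffer combination.
- **Synthetic data** (`liverqtl.simulate`) — seeded generators for
  genotypes in Hardy–Weinberg proportions (with a hemizygous-male X
  block), expression with planted cis effects on both the latent-normal
  and TPM scales, sample swaps, exon-usage counts with planted sQTLs,
  equicorrelated multi-dataset TWAS z panels, tissue posterior matrices,
  and gene-set catalogs with planted enrichment.

## Command-line interface

One `liverqtl` entry point with subcommands:

```bash
# generate a full synthetic cohort (TSV/VCF/GMT/JSON outputs)
liverqtl simulate --config config.yaml --outdir sim/ --seed 3

# sample QC report (exit code 1 if any sample is flagged)
liverqtl qc --genotypes sim/genotypes.tsv --tpm sim/tpm.tsv \
    --counts sim/counts.tsv --annotation sim/annotation.tsv \
    --reported-sex sim/reported_sex.tsv --k 100 --out qc.tsv

# filtering, normalization, covariates
liverqtl preprocess --genotypes sim/genotypes.tsv --tpm sim/tpm.tsv \
    --counts sim/counts.tsv --annotation sim/annotation.tsv \
    --factors 30 --outdir pre/

# cis scan + eGene permutations; trans scan + clumping + flags
liverqtl map-cis --genotypes pre/genotypes_filtered.tsv \
    --expression pre/expression_int.tsv --covariates pre/covariates.tsv \
    --annotation sim/annotation.tsv --perm 1000 --outdir cis/
liverqtl map-trans --genotypes pre/genotypes_filtered.tsv \
    --expression pre/expression_int.tsv --annotation sim/annotation.tsv \
    --qmax 0.1 --outdir trans/

# splicing QTLs on exon counts
liverqtl sqtl --exon-counts sim/exon_counts.tsv \
    --genotypes sim/genotypes.tsv --annotation sim/annotation.tsv \
    --n-perm 1000 --seed 1 --out sqtl.tsv

# gene-set enrichment with heterogeneity tests
liverqtl enrich --egenes cis/egenes.tsv --sets sim/gene_sets.gmt \
    --p-thr 1e-5 --out enrich.tsv

# tissue clustering + liver specificity
liverqtl specificity --posteriors sim/posteriors.tsv \
    --liver UNC_Liver,GTEx_Liver --top 200 --outdir spec/

# omnibus TWAS and its calibration simulation
liverqtl twas --panel sim/zpanel.tsv --outdir twas/
liverqtl twas-calibrate --rho 0.5 --datasets 6 --genes 10000 --reps 20 \
    --out calib.tsv
```

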