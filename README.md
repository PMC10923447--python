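# grstrat

Genetic-risk-score (GRS) stratified asthma phenotyping, packaged as a tested
pipeline over synthetic cohorts:

1. **Variant panel** (`grstrat.panel`) — candidate-SNP filter chain
   (MAF ≥ threshold, imputation r² screen, greedy LD pruning), chip-style
   genotype QC (call rates, MAF, Hardy-Weinberg exact test in controls) and
   the unweighted allele-count GRS (sum of risk-allele dosages over the
   panel; missing dosages count as 0 by default, mean imputation by flag).
2. **Two-step clustering** (`grstrat.twostep`) — patients clustered on
   (GRS, %predicted FEV₁, age of onset): z-standardization, agglomeration
   from singletons under the log-likelihood merge distance, BIC trace, and a
   two-stage automatic cluster count (BIC-change ratio 0.04, distance-change
   ratio 1.15).
3. **Association statistics** (`grstrat.stats`) — one-way ANOVA, Tukey HSD
   (raw and summary-statistic forms via the studentized-range distribution),
   Kruskal-Wallis, r×c chi-squared with adjusted standardized residuals,
   allele-based 2×2 association with Haldane-Anscombe-corrected odds ratios,
   inverse-variance fixed-effect meta-analysis (Q, I²), covariate-adjusted
   logistic association and logistic gene-gene interaction tests.
4. **Synthetic cohorts** (`grstrat.simulate`) — multi-cohort case-control
   data: HWE genotypes with Gaussian-copula within-block LD, and a latent
   phenotype mixture whose cluster membership is tilted by a centered
   genotype score (log-odds slope δ per cluster; `mode="null"` severs the
   genotype-phenotype link). One root seed, one child stream per cohort.
5. **Pipeline** (`grstrat.pipeline`, `grstrat.cli`) — per cohort:
   GRS → cluster → letter labels A.. by decreasing mean GRS → Tukey contrast
   vs healthy → GRS-extreme cluster selection; across cohorts: Hi/Lo/average
   combined groups, per-SNP Lo-vs-Hi allele contrasts (Hi as reference) with
   per-SNP meta-analysis, and a combined-group phenotype summary table.

A 12-SNP ciliary-gene panel and a three-cohort simulation scenario are
packaged as defaults (`grstrat/data/`).

## CLI

```bash
# full pipeline on the packaged default scenario
grstrat run-all --out-dir out/ --seed 1 --mode planted

# individual stages
grstrat simulate --config cfg.yaml --out-dir sim/ --seed 1 --mode planted
grstrat grs --genotypes sim/genotypes_c1.tsv --out sim/grs.tsv
grstrat cluster --phenotypes sim/phenotypes_c1.tsv --grs sim/grs.tsv \
    --out-dir sim/ --cohort c1
grstrat contrast --membership out/groups.tsv \
    --genotypes c1=sim/genotypes_c1.tsv --out-dir out/
grstrat report --run-dir out/
```

`run-all` writes, per cohort, cluster assignments, per-cluster GRS
summaries, Tukey-vs-healthy tables and the model JSON (BIC trace, merge
distances, selection report), plus pooled group membership, per-SNP and
meta association tables, the combined-group summary with adjusted
residuals, and a manifest with the seed and config digest. Re-running with
the same seed and config reproduces every report byte-for-byte.

## File formats

- Dosage TSV: rows = samples, columns = rsids, values 0/1/2, `NA` missing.
- Panel TSV: `rsid chrom pos gene risk_allele other_allele consequence maf
  imputation_r2 genotyped`.
- Phenotype TSV: `sample_id cohort status sex age onset_age fev1_pct
  fev1_fvc bmi smoking_status smoking_index atopy log_ige eos_pct
  eosinophilic`.
- VCF: GT-only, one sample per individual; dosages are oriented to the
  panel's risk allele on read (strand harmonisation is the caller's
  responsibility).
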