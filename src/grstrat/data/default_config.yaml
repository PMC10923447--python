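# Default three-cohort synthetic scenario.
#
# Cohort sizes follow the published study populations (565/537, 965/242,
# 673/446 healthy/case).  The 12 variants carry the packaged panel's rsids
# and risk alleles; risk-allele frequencies for rs2277046 (0.49) and
# rs1530496 (0.31) follow the printed MAF column, the others are fixed
# placeholder values in [0.1, 0.5].  rs1530496 gets a larger tilt weight so
# that planted-mode data carry one dominant cluster-associated SNP.
# Clusters echo the published phenotype patterns: two GRS-extreme components
# (A high, D low) that are late-onset with preserved lung function, one
# obstructed component (B) and one early-onset component (C).
seed: 0
mode: planted
missing_rate: 0.0
cohorts:
  - {name: cohort1, n_healthy: 565, n_case: 537}
  - {name: cohort2, n_healthy: 965, n_case: 242}
  - {name: cohort3, n_healthy: 673, n_case: 446}
variants:
  - {rsid: rs3795958,  gene: CCDC164, chrom: "2",  pos: 26635489, risk_allele: G, other_allele: A, freq: 0.35, ld_block: CCDC164, block_r2: 0.05}
  - {rsid: rs12623642, gene: CCDC164, chrom: "2",  pos: 26642219, risk_allele: T, other_allele: C, freq: 0.42, ld_block: CCDC164, block_r2: 0.05}
  - {rsid: rs2277046,  gene: DNAH5,   chrom: "5",  pos: 13717471, risk_allele: G, other_allele: A, freq: 0.49, ld_block: DNAH5, block_r2: 0.05}
  - {rsid: rs10513155, gene: DNAH5,   chrom: "5",  pos: 13802166, risk_allele: T, other_allele: C, freq: 0.33, ld_block: DNAH5, block_r2: 0.05}
  - {rsid: rs1530498,  gene: DNAH5,   chrom: "5",  pos: 13929842, risk_allele: G, other_allele: A, freq: 0.38, ld_block: DNAH5, block_r2: 0.05, consequence: utr3}
  - {rsid: rs1530496,  gene: DNAH5,   chrom: "5",  pos: 13931340, risk_allele: A, other_allele: G, freq: 0.31, ld_block: DNAH5, block_r2: 0.05, consequence: utr3, tilt_weight: 5.0}
  - {rsid: rs2285943,  gene: DNAH11,  chrom: "7",  pos: 21583128, risk_allele: T, other_allele: G, freq: 0.44, ld_block: DNAH11, block_r2: 0.05}
  - {rsid: rs10224537, gene: DNAH11,  chrom: "7",  pos: 21639861, risk_allele: G, other_allele: T, freq: 0.36, ld_block: DNAH11, block_r2: 0.05}
  - {rsid: rs2214326,  gene: DNAH11,  chrom: "7",  pos: 21752446, risk_allele: A, other_allele: G, freq: 0.4, ld_block: DNAH11, block_r2: 0.05}
  - {rsid: rs7971,     gene: DNAH11,  chrom: "7",  pos: 21941485, risk_allele: G, other_allele: C, freq: 0.32, ld_block: DNAH11, block_r2: 0.05}
  - {rsid: rs10250905, gene: TXNDC3,  chrom: "7",  pos: 37893459, risk_allele: C, other_allele: T, freq: 0.47}
  - {rsid: rs600753,   gene: DYX1C1,  chrom: "15", pos: 55790530, risk_allele: G, other_allele: A, freq: 0.43}
clusters:
  - {name: A, weight: 0.27, grs_delta:  3.0, onset_mean: 52, onset_sd: 9,  fev1_mean: 95, fev1_sd: 12, female_prob: 0.65, atopy_prob: 0.60, eos_prob: 0.40}
  - {name: B, weight: 0.22, grs_delta:  0.0, onset_mean: 50, onset_sd: 11, fev1_mean: 53, fev1_sd: 10, female_prob: 0.44, atopy_prob: 0.70, eos_prob: 0.50}
  - {name: C, weight: 0.21, grs_delta:  0.0, onset_mean: 8,  onset_sd: 6,  fev1_mean: 81, fev1_sd: 14, female_prob: 0.54, atopy_prob: 0.85, eos_prob: 0.48}
  - {name: D, weight: 0.30, grs_delta: -3.0, onset_mean: 58, onset_sd: 9,  fev1_mean: 98, fev1_sd: 12, female_prob: 0.58, atopy_prob: 0.55, eos_prob: 0.38}
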