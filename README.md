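# svmolqtl

Structural variants (SVs — deletions, insertions, duplications and
inversions of ≥ 50 bp) are disproportionately likely to alter gene
expression and splicing, yet they are harder to genotype than SNPs and short
indels, and both missing genotypes and het→hom miscalls bias the association
tests used to find molecular QTL (molQTL). `svmolqtl` implements, as a
tested Python library plus a set of analysis drivers, the downstream
statistics of a long-read cattle cohort study of this problem:

- **Permutation-based cis-molQTL mapping.** For each molecular feature
  (gene, or grouped intron clusters for splicing), every variant within
  1 Mb of the feature start with MAF ≥ 1% and missingness < 10% is tested by
  OLS of the inverse-normal-transformed phenotype on the alternate-allele
  dosage plus covariates, fitted on exactly the samples with a non-missing
  dosage for that variant (casewise deletion). A permutation pass (default
  1000 label permutations per feature) records the minimum nominal p per
  permutation and fits a Beta distribution by maximum likelihood; the
  feature-level adjusted p is the Beta CDF at the observed minimum,
  `p_adj = F_Beta(min_v p_v; α̂, β̂)`. Gene-level discovery is controlled at
  5% FDR (Storey q-values, BH fallback) and per-feature nominal thresholds
  are recovered by inverting the Beta fit at the FDR boundary. A
  forward-backward conditional analysis decomposes significant features
  into independent signals.
- **SV molQTL definition and enrichment.** A signal is an *SV molQTL* when
  an SV attains the signal's minimum p — strictly smallest or exactly tied
  with the lead small variant. SV enrichment among top variants is a Fisher
  exact test on unique lead variants against the tested variant sets, with
  both the sample odds ratio and the proportion-ratio fold reported.
- **Perfect-LD rescue.** Signals led by a small variant are re-examined for
  SVs in complete LD (r² = 1 over pairwise-complete samples) with the lead
  but a larger p-value; because each variant's regression is fitted on its
  own missingness subset, such gaps are attributable to unequal missing
  genotypes, and counting these signals as SV-associated yields an
  augmented enrichment.
- **Coverage-based duplication genotyping.** Duplication genotypes are
  assigned from mean depth in 500-bp windows relative to the chromosomal
  background: fold change ≥ 1.3 calls a heterozygote, ≥ 1.8 a homozygote.
- **Robustness experiments.** Synthetic-cohort experiments quantify the
  loss of SV molQTL detection as het→hom genotyping error accumulates and
  the p-value bias between perfect-LD pair members as genotypes of one
  member go missing, plus cohort summaries (SV discovery saturation,
  singleton accounting, per-sample heterozygosity).

Everything runs on a synthetic cohort generator (`svmolqtl.simdata`) that
emulates the study design — 120 diploid samples, LD-block genotypes with an
MAF spectrum down to 1%, SVs at realistic per-window density, perfect-LD
small-variant/SV pairs, class-specific missingness (~1.2% small, ~5.3% SV),
2% het→hom errors on SV genotypes, planted cis effects on the
inverse-normal scale, and 13.5× depth tracks — so every stage is testable
against known ground truth.

## Worked example

The numbered drivers under `analysis/` run the full pipeline; each writes
tables under `results/` and prints what it found.

```bash
python analysis/01_published_accounting.py
python analysis/02_simulate_cohort.py
python analysis/03_map_molqtl.py
python analysis/04_sv_enrichment.py
python analysis/05_coverage_genotyping.py
python analysis/06_robustness.py
```

Script 01 rebuilds the published-cohort contingency tables from the printed
counts:

```
eqtl: SV top variants 2.05-fold enriched (Fisher p = 9.29e-11)
sqtl: SV top variants 5.59-fold enriched (Fisher p = 1.92e-70)
eqtl: 0.6% of independent signals are SV-led
MSY small-variant count increased by 244.0% with long reads
```

Scripts 02–04 generate a 120-sample cohort (202 variants, 18 SVs, 14
phenotypes including a 3-member grouped feature and two planted perfect-LD
pairs), write it as VCF / QTLtools-dialect BED / TSV, map it, and classify
the leads:

```
10/14 features significant at 5% FDR; 12 independent signals
planted features recovered: 8/8
2 SV-led / 12 signals; baseline SV enrichment fold = 2.56 (p = 0.22)
perfect-LD rescue: 1 rescued SV pairs; augmented fold = 4.38 (baseline 2.56)
```

The rescue line is the mechanism of interest in miniature: an SV that
drives a phenotype but carries more missing genotypes than a perfectly
linked SNP loses the lead by a hair's breadth of sample composition, and
re-attributing such signals raises the SV enrichment — here from 2.6- to
4.4-fold. Script 05 demonstrates the coverage genotyper (het F1 = 0.97 with
four planted miscalls; correcting the miscalled carriers strengthens the
association from p = 1.2e-17 to 3.7e-18), and script 06 shows SV molQTL
detection declining with injected error rate and the perfect-LD p-value gap
growing with the number of masked genotypes.

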