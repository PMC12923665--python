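# Methods

## Scope and model

The package re-creates the downstream statistics of a cohort molQTL study:
given diploid genotypes (small variants and SVs), normalised molecular
phenotypes and covariates, it maps cis-acting QTL by permutation testing,
classifies lead variants by class, measures SV enrichment, attributes
near-miss SV signals to genotype missingness, genotypes duplications from
read depth, and quantifies how genotyping error and missingness distort
detection. Upstream steps — sequencing, alignment, variant calling,
transcript quantification — are out of scope; their products are emulated
by a synthetic generator with known ground truth.

## Association model

For feature *f* with normalised phenotype *y* and variant *v* with dosage
*g<sub>v</sub>* ∈ {0, 1, 2, missing}:

y = μ + g_v β_v + C γ + ε,

fitted by OLS on exactly the samples with a non-missing dosage for *v*
(casewise deletion), with a two-sided t-test on β̂<sub>v</sub>. Missing
dosages are never imputed in association tests — preserving the missingness
mechanism is the point of the analysis. Internally, variants sharing a
missingness pattern are processed jointly: the covariates are
QR-orthogonalised on that pattern's sample subset and the t statistic is
computed from the partial correlation of the residualised dosage and
phenotype. By the Frisch–Waugh theorem this is exactly the per-variant
refit; it is not an approximation, only a factorisation that lets one
matrix product evaluate thousands of permutations.

Variants are testable for a feature iff |pos − anchor| ≤ 1 Mb (inclusive),
MAF ≥ 1% (computed over non-missing alleles) and missing fraction < 10%.
The anchor is the feature's strand-aware start site (BED start for +, end
for −; configurable to strand-naive). A variant is untestable when fewer
than (number of covariates + 2) samples survive casewise deletion.

## Permutation pass and Beta approximation

Per feature, phenotype values are permuted against fixed genotypes and
covariates; one shared permutation sequence serves all of the feature's
variants, seeded per feature from the global seed so results are
reproducible and features are independent. The minimum nominal p per
permutation is recorded (default 1000 permutations; at least 100 enforced).
A two-parameter Beta distribution is fitted to the permuted minima by
Nelder–Mead maximum likelihood from method-of-moments starting values; on
failure the empirical estimator is used instead. The adjusted p is the Beta
CDF at the observed minimum; the empirical p uses (1 + k)/(1 + B) to avoid
zeros. Grouped (splicing-style) features draw one permutation per group per
round and take the minimum across all member × variant pairs; the reported
feature is the member attaining the observed minimum.

## FDR and per-feature thresholds

Q-values use Storey's π₀ (smoother method: cubic fit of π₀(λ) over
λ ∈ {0.05, …, 0.95}, evaluated at the largest λ), falling back to
Benjamini–Hochberg (π₀ = 1) when fewer than 20 features are available or
the estimate is degenerate. Features with q ≤ 0.05 are e/sGenes. The
adjusted-p cutoff is the midpoint between the largest significant and
smallest non-significant adjusted p; each significant feature's nominal
threshold is the inverse Beta CDF of that cutoff at its own (α̂, β̂). This
back-computation follows the convention of the standard QTL toolchain's FDR
script; the exact original procedure is not fully specified, so this is
documented as the package's construction.

## Conditional analysis

Forward: iteratively add the current best variant (p ≤ feature threshold)
to the covariates and re-scan; stop when nothing passes or the lead set
becomes collinear (newest lead dropped with a warning). Backward: re-test
each candidate conditioning on all other retained leads; conditionally
passing variants form the signal's significant set and the lead is the
minimum conditional p. Conditioning dosages are mean-imputed so that each
tested variant keeps its own casewise-deletion subset; the tested variant
itself is never imputed.

Ties at the minimum p (relative tolerance 1e−12, absorbing formatting
noise) are resolved SV-first, then leftmost position — the SV-preferring
rule is the published definition of an SV molQTL, under which a signal is
SV-led when an SV is strictly smallest *or* exactly tied with the lead
small variant.

## Enrichment and rescue

SV enrichment among top variants uses the 2×2 table of unique lead
variants vs non-lead tested variants per class; both the sample odds ratio
ad/bc and the proportion-ratio fold are reported with a two-sided Fisher
exact p. Reconstructing the published count table with this unique-top
construction reproduces the printed 2.1-fold (expression) and 5.6-fold
(splicing) enrichments; alternative constructions (signal counts rather
than unique variants) are computable from the same function. Functional
annotation overlap uses ≥ 1 bp intersection by default and ≥ 50%
containment for tandem-repeat classing; no multiple-testing correction is
applied across annotations, matching the source analysis.

Perfect-LD rescue: for each small-led signal, SVs within the window with
r² ≥ 1 − 1e−9 to the lead (pairwise-complete samples) are re-tested; those
with a strictly larger p are rescue candidates, annotated with both
variants' missing-genotype counts. With no missingness anywhere the two
regressions are identical and nothing is rescued. The augmented enrichment
moves rescued signals from the small to the SV column, so it can only rise.

## Coverage genotyping

Mean depth per 500-bp window; the chromosome background is the mean over
windows outside the duplication; the region fold change is the
length-weighted mean over overlapping windows (partial windows weighted by
overlap — the weighting is the package's choice, as the source does not
state one). Thresholds are inclusive: fold ≥ 1.3 → 0/1, ≥ 1.8 → 1/1,
making the genotype monotone in fold change. Only duplications are
coverage-genotyped.

## Synthetic cohort generator

Genotypes: per LD block, each sample carries two haplotype latents
z ~ N(0,1); variant *j* on a haplotype is the alternate allele iff
√ρ·z + √(1−ρ)·ε < Φ⁻¹(maf_j), with ρ = 0.9 by default. Marginal allele
frequencies are exact, dosages are Hardy–Weinberg, and within-block LD is
governed by ρ. Defaults follow the study conditions: 120 samples, MAF drawn
in [0.01, 0.5], SV missingness 5.3% vs 1.2% for small variants
(joint-called SV rate before force-calling vs the small-variant rate), 2%
het→hom error on SV genotypes, 13.5× depth in 500-bp windows with 1.5×/2.0×
duplication fold changes. The SV fraction defaults to 10% of simulated
variants: cis windows in the study contained a few SVs among tens of
testable variants per feature, and the desk-scale blocks reproduce that
per-window density rather than the genome-wide SV:SNV ratio. SV types skew
to insertions, as long-read catalogues do. Perfect-LD pairs duplicate a
(preferentially common) small variant's dosage vector as an SV record.

Planted effect sizes are interpreted on the INT scale: since the rank-based
transform standardises the phenotype, the generator root-finds the raw
slope whose asymptotic INT-scale regression coefficient (computed from the
mixture-of-normals quantile map) equals the requested β. A residual
finite-sample attenuation of roughly 2% at n = 120 remains, small relative
to the sampling error of any single estimate. An INT-scale β is bounded by
the reciprocal dosage SD; requesting more raises an error. A `beta_scale=
"raw"` option plants directly on the pre-transform scale instead.

Phenotypes add two known covariates (age- and RIN-like, N(0,1) with slopes
0.3/0.2) and unit Gaussian noise, then apply the rank-based INT with
(rank − 0.5)/n offset and average ranks for ties. Grouped features share
the group id and planted effect with independent member noise. Expression
preparation quantile-normalises across samples and then transforms;
QN-induced rank ties are broken by the raw values so each feature is an
exact permutation of the INT quantile vector, while genuinely tied raw
values stay tied.

Corruption order is missingness first, then errors (errors only touch
non-missing hets), keeping the two logs disjoint; both logs store original
values so the clean matrix is exactly reconstructible. Missingness can
optionally scale with a per-sample coverage factor, mimicking the observed
association of residual missingness with low alignment coverage; the
default is independent, as the true mechanism is not established.

Depth tracks use Gaussian window noise with SD √(mean depth), truncated at
zero (Poisson-like; the source states no noise model), and a mild lognormal
per-sample depth scale.

## What the simulations do and do not show

Passing tests establish that the statistical machinery behaves as claimed
under the generator's assumptions: unlinked blocks, a single latent LD
dimension, Gaussian phenotype noise, missingness independent of genotype,
and errors confined to het→hom flips. Real cohorts add population
structure, LD decay within blocks, phenotype heavy-tails partially absorbed
by INT, and missingness correlated with genotype and locus complexity —
none of which the desk-scale cohort reproduces. Results on synthetic data
therefore validate the implementation, not the biology.

## Experiment design and problem sizes

Error draws in the sensitivity experiment are coupled across the epsilon
grid (the same uniforms thresholded at each rate), so the set of flipped
genotypes is nested and detection differences reflect the error rate, not
resampling noise. Masked-sample sets in the missingness experiment are
likewise nested across grid points. Detection of a planted SV molQTL means:
feature significant at 5% FDR *and* lead classified SV under the tie rule.

The shipped tests and the acceptance script use desk-scale problems chosen
to make each check statistically decisive: 500 features for null FDR
calibration (bound 0.05 + 3·MC error), 100,000 direct permutations when
validating the Beta approximation (tolerance 2·MC error of the
1000-permutation estimate), 50 replicate cohorts for power and bias, and
20 replicates across the error grid {0, 0.02, 0.05, 0.1}. Power/bias
cohorts plant β = 0.7 at causal MAF ≥ 0.2: at n = 120 this gives a nominal
z ≥ 4.3, the regime where a 90% power claim is meaningful — at the extreme
corner of the testable ranges (MAF 0.1, β 0.5) the nominal z is ~2.3 and no
method attains 90% power. Monotonicity assertions on median curves carry
an explicit Monte-Carlo slack.

## Known limitations

- The Beta fit is unweighted two-parameter MLE without the effective-test
  correction some tools apply; its accuracy is verified empirically against
  direct permutations rather than assumed.
- Storey's smoother uses a cubic polynomial fit of π₀(λ); with very few
  features the BH fallback makes q-values conservative.
- The conditional analysis mean-imputes conditioning dosages; with heavy
  missingness on a lead this blurs the conditioning, though the tested
  variant's own subset is always exact.
- `ld_prune` is O(w²) per window — fine at cohort scale here, not tuned for
  millions of variants.
- Hemizygous calls are coded 0/2 by default (configurable); mixed-ploidy
  cohorts beyond that convention are untested.
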