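# Methods

## The estimator

For each SNP the package holds a pair of observed p-values, (P_i, P_j), for
a primary and a secondary trait from two GWAS with non-overlapping samples.
The conditional FDR is

    cFDR(i|j) = Pr(H0(i) | p_i ≤ P_i, p_j ≤ P_j) = p_i / Pr(p_i ≤ P_i | p_j ≤ P_j),

a local-FDR-style posterior probability of the primary-trait null given the
joint tail event. The denominator is the raw empirical conditional
proportion over all n SNPs in the analysis table:

    #{l : p_i[l] ≤ P_i and p_j[l] ≤ P_j} / #{l : p_j[l] ≤ P_j}.

Conventions, chosen for determinism and numerical safety:

* **Self-inclusion.** The index SNP counts in both numerator and
  denominator, so every estimate lies in (0, 1] and no division by zero can
  occur (the SNP with the strictly smallest secondary p-value conditions on
  itself alone and gets denominator 1, hence cFDR = p_i).
* **Ties.** All comparisons are non-strict on the stored values; no
  jittering. In the degenerate limit of a constant secondary vector the
  estimator collapses to the empirical CDF with max-rank tie handling and
  cFDR = min(1, p·n/rank), which the tests assert exactly.
* **Capping.** The ratio is capped at 1: it estimates a probability, and
  uninformative conditioning can push the raw ratio above 1.
* **No smoothing, no overlap correction.** No kernel density, binning or
  monotone regression is applied to the denominator, and no shared-control
  adjustment is made (the intended use case is two disjoint cohorts).

The estimator is implemented twice with an identical contract: an O(n²)
dominance-count reference, and the production O(n log n) path that sweeps
SNPs in secondary-p order and accumulates rank-compressed primary-p counts
in a Fenwick tree, inserting each group of tied secondary values before
answering its queries. The test suite asserts entry-for-entry equality on
random instances with heavy ties; the reference is never used to produce
results, only to check them.

The conjunctional cFDR is the elementwise maximum of the two directional
cFDRs, and classification at threshold α (default 0.01, inclusive) labels a
SNP pleiotropic iff ccFDR ≤ α, otherwise primary-/secondary-only iff the
corresponding directional cFDR passes. Because max(a, b) ≤ α iff both pass,
the labels are mutually exclusive by construction.

This raw empirical-ratio estimator is not an FDR-controlling procedure in
the Benjamini–Hochberg sense; the suite asserts only that under a global
null the fraction of SNPs at cFDR ≤ 0.01 stays small (< 5% in expectation
over replicates), not exact calibration.

## Harmonisation

The two input tables are merged on rsID (optionally rsID+position). Allele
pairs must match either directly or with effect/other swapped; a swap
aligns the secondary effect by negation (beta) or inversion (odds ratio)
and is flagged. Mismatched pairs are dropped and counted. Strand-ambiguous
A/T and C/G SNPs are retained and matched literally by default — an
explicit `drop_ambiguous` flag excludes them — because p-value-based
conditioning is unaffected by strand so long as the same physical variant
is paired. p ≤ 0 is clamped to the smallest positive double rather than
dropped (the most extreme hits are precisely the ones worth keeping);
p > 1 invalidates the row. Duplicates keep the first occurrence in input
order.

## LD pruning

Greedy indep-pairwise semantics: per chromosome, windows of 50 consecutive
*currently retained* SNPs; while any within-window pair has r² > 0.2
(squared Pearson correlation of dosages over pairwise-complete samples),
one member is removed; the window then slides 5 retained SNPs along. The
removal tie-break is total and documented — higher missingness first, then
lower MAF, then the later (chrom, pos) — which keeps better-genotyped, more
informative variants and makes output order-independent of floating-point
incidentals. Pairs involving a zero-variance vector get r² = 0 (not
prunable); a `drop_monomorphic` flag removes MAF = 0 SNPs up front.
Windows are SNP-counted, not kb-based, and the tests assert the documented
tie-break behaviour, not fidelity to any particular external tool run.

## Gene context

Genes overlapping ±0.5 Mbp around a SNP (radius, adjustable) are reported
with distance to the nearer edge (0 within the span) and a strand-aware
relation: 5′ of the gene is upstream. Gene tables are 1-based inclusive
TSVs — deliberately not BED's 0-based half-open — so hand-written fixtures
read naturally; add 1 to BED starts when converting.

## Follow-up regressions

Logistic (statsmodels `Logit`) and proportional-odds cumulative-logit
(statsmodels `OrderedModel`, logit link) models of a phenotype on SNP
dosage plus age and sex, optionally plus the other phenotype. Genotype
p-values use the normal approximation to beta/SE in both model classes.
The ordinal fit standardises the nuisance covariates internally for
optimiser conditioning (BFGS, gradient tolerance 1e-8); the dosage slope,
its SE and the log-likelihood are invariant to that reparametrisation, and
a two-level ordinal outcome reproduces the logistic fit to < 1e-6.

McFadden's pseudo-R² is reported two ways, because "variance explained by
genotype, adjusting for covariates" is ambiguous: the full-model value
1 − ll_full/ll_null, and the genotype increment over the covariates-only
model. Benjamini–Hochberg adjustment is applied to the explicit family of
genotype p-values from one invocation — family membership is never
implicit. The attenuation comparison fits the outcome with and without the
other phenotype as adjuster and verdicts "attenuated" when genotype
significance (p ≤ 0.05) is lost upon adjustment. All analyses are
complete-case per model.

## Synthetic data

* **Summary-statistic pairs.** Each SNP draws a class from
  π = (null, trait1-only, trait2-only, pleiotropic), default
  (0.95, 0.02, 0.02, 0.01) — a mostly-null genome with a small pleiotropic
  component. Non-null classes draw latent effects δ ~ N(0, τ²) on the
  z-score scale (τ = 3 by default, comfortably detectable), pleiotropic
  SNPs a bivariate pair with correlation ρ = 0.53, the genetic correlation
  reported between chronic pain grade and MDD. Observed
  z = δ·√n + ε with independent standard-normal ε per trait (disjoint
  cohorts), p = 2Φ(−|z|). Working on the z scale avoids committing to any
  MAF–beta coupling, which a p-value-only method never uses. The induced
  corr(z1, z2) in the pleiotropic class, ρτ₁τ₂√(n₁n₂)/√((τ₁²n₁+1)(τ₂²n₂+1)),
  is exposed for tests. Positions sit at 1 kb spacing; rsids count from
  rs900000001, clear of real identifiers.
* **Genotypes.** Latent Gaussian AR(1) within blocks, independent across
  blocks, thresholded to Hardy–Weinberg dosage frequencies at the target
  MAF. AR coefficient 0.95 on 5-SNP blocks gives adjacent-pair r² well
  above the 0.2 pruning threshold at 500 samples.
* **Cohorts.** Dosage ~ Binomial(2, f); age ~ N(57, 8); P(female) = 0.54;
  chronic-pain prevalence ≈ 0.43 and depression prevalence ≈ 0.28 —
  population-cohort-like values. Ordinal phenotypes come from
  proportional-odds mechanisms whose first threshold defines the
  dichotomous variable, so category 0 ⟺ control holds by construction and
  the dichotomised margin is exactly a logistic model with the same
  slopes. Under `mediation=True` depression depends on the pain phenotype
  (log-OR ln 2 by default), age and sex, but not directly on genotype —
  mediated (vertical) pleiotropy; `mediation=False` adds a direct
  genotype term (biological/horizontal pleiotropy).

What the generators do **not** emulate: realistic (coalescent) LD and
allele-frequency spectra, population stratification, relatedness, sample
overlap between the two GWAS, assortative measurement error, or missing
data. Passing tests therefore demonstrate correctness of the estimators
and procedures under the stated generative models, not robustness to those
real-data complications.

## Problem sizes and stochastic checks

The test suite runs the estimator-equivalence check on 50 random instances
up to n = 2,000; global-null behaviour on 200 replicates of 50,000 SNPs;
regression parameter recovery on 100 replicates at n = 50,000 (asserting
the truth inside the fit's own 95% CI in ≥ 90 of them); and the
mediation-attenuation check on 100 replicates at n = 100,000 with a
per-allele pain OR of 1.3 — sized, by a power analysis of the mediated
effect against the per-replicate sampling SD, so that the ≥ 90%-of-seeds
assertion has high power. At a weaker, more realistic chain
(OR 1.02, n = 400,000) the attenuation remains clearly visible in the
paired difference of coefficients (mean shrinkage ≈ 0.0036, SD ≈ 0.0007)
but single-replicate magnitude comparisons succeed in only ~60% of seeds;
the per-seed criterion is therefore evaluated at the stronger chain.

## Known limitations

* The denominator is a step function of the observed pairs; for very small
  conditioning sets the cFDR is noisy, and no v-value / leave-one-out
  refinement is implemented.
* Pruning fidelity is to the documented greedy semantics and tie-break,
  not to any specific external implementation whose tie-break is
  unpublished.
* The ordinal models assume proportional odds; no test of that assumption
  is provided.
* No liftover, imputation-quality filtering, genomic control, or formal
  causal mediation analysis.
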