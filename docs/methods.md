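# Methods

## Model and assumptions

The package models the probability of disease given a polygenic risk score
(PRS) under three assumptions:

1. **Within-group normality.** The PRS is normally distributed within cases
   and within non-cases. For a score aggregating thousands of weak,
   approximately independent SNPs this follows from the central limit
   theorem; for oligogenic scores built from a few dozen SNPs it is an
   approximation, and the validation ladder (below) quantifies the cost.
2. **The raw posterior is the case fraction.** Bayesian inversion of the
   two group densities with prevalence K is taken to give the true fraction
   of cases at each score value.
3. **Layer independence.** Rare-variant effects are independent of the
   polygenic background, and the distribution of a PRS computed without a
   high-effect variant's region is the same in every genotype stratum of
   that variant.

With equal group variances the Bayesian log odds is exactly affine in the
score and the closed-form coefficients coincide with the
discriminant-analysis solution. With unequal variances the log odds is
quadratic; the model deliberately keeps the *linear* logit form — matching
what a logistic regression on case/control data would estimate — by
projecting the quadratic onto a line with the population mixture density as
weight. The closed form is that projection evaluated analytically; the
package retains it verbatim rather than substituting a quadratic model, and
cross-checks it against an explicit weighted least-squares fit on a dense
grid (2,001 points over the population mean ± 8 population SDs; weight mass
beyond 8 SDs is negligible at double precision, and the odd count places a
grid point on the mean).

## Parameters

| parameter | meaning | units | typical value |
|---|---|---|---|
| K | disease prevalence in the (sub)population | probability | 0.02 lifetime, 0.10 at 65+, 0.30 at 85+ for Alzheimer's |
| m1, σ1² | PRS mean/variance in cases | score units | study-specific |
| m0, σ0² | PRS mean/variance in non-cases | score units | study-specific |
| OR (rare) | odds ratio of a rare risk variant | — | 7.2 (SORL1-like), 2.46 (TREM2-like), ~500 (APP/PSEN-like) |
| f, OR (high-effect) | risk-allele frequency and odds ratio of a common high-effect variant | — | 0.18 and 3.2 (APOE-ε4-like, 55+) |

The PRS itself uses the convention PRS_j = (1/N_snps) Σ g_ij β_i with
dosage g counting copies of the named effect allele, and sample variance
with the 1/N divisor (population variance). The 1/(N−1) convention is more
common in software; the 1/N form is used here for individual-data scoring,
and the difference is immaterial downstream because the calibration uses
whatever moments are supplied, requiring only internal consistency. A VCF
reader flips dosages (2−g) when the effect allele is the REF allele;
matching is by SNP id and allele, never by position.

## Numerical choices

* All density arithmetic is in log space: the raw probability is formed as
  `expit` of a log-odds difference, never as a ratio of raw normal
  densities, so curves are finite and monotone ±10 SDs into the tails.
* The closed form for the genotype-stratified prevalences divides by
  (1−OR); at OR = 1 the singularity is removable and the analytic limit
  ν = K(1−f) is used whenever |OR−1| < 1e-8. Continuity across the switch
  is verified to 1e-4.
* The non-case variance implied by unscreened-control inversion is required
  to be positive; non-positive values raise an error rather than being
  clamped, since they signal mutually inconsistent summary inputs.
* Genotype prevalences outside [0,1] — which arise when a strong or very
  common risk allele meets a higher prevalence, where HWE in non-cases no
  longer approximately holds — likewise raise rather than clamp. No
  correction for high-prevalence diseases is attempted.
* Rare variants with OR ≤ 1 are rejected: the intrinsic-probability model
  treats the variant as an independent cause of disease, which has no
  analogue for protective alleles. An allele frequency above 0.005 on a
  rare variant logs a warning, as the fixed-K assumption becomes doubtful.
* Constant score vectors fail moment construction (zero variance) rather
  than propagating degenerate curves.

## Simulation machinery and what it emulates

The generator draws independent SNPs in Hardy–Weinberg equilibrium within
each group: control-group allele frequencies and per-SNP log odds ratios
define the case-group frequencies through allelic odds scaling
f_case = OR·f/(1+f(OR−1)). Samples are balanced (equal cases and controls),
as case/control studies are; fitted intercepts are re-anchored to the
population prevalence by adding log(K/(1−K)) − log(n_cases/n_controls), so
every fitted curve is on the population-probability scale the closed form
produces directly. Randomness is governed by one root seed, split
deterministically per group, so reports are exactly reproducible.

Two stock scenarios bracket realistic score constructions:

* **Oligogenic (ORS-like):** 39 SNPs, odds ratios 1.1–1.4, minor allele
  frequencies 0.05–0.5.
* **Polygenic (PRS-like):** the same 39 strong SNPs plus 10,000 weak SNPs
  with odds ratios 1.001–1.04. The weak-SNP effects are kept close to null
  so that the aggregate score separates case and control means by roughly
  1.2 SDs (AUC ≈ 0.8), in line with reported Alzheimer's PRS accuracy;
  materially larger per-SNP effects at this SNP count would separate the
  groups completely and make the maximum-likelihood logistic fit — the very
  thing being validated — unidentifiable.

The default validation runs 10,000 cases + 10,000 controls and compares
four curves on the standardised [−4, 4] axis: the closed form, ML logistic
regression on the simulated-genotype PRS, ML logistic regression on normal
score draws at the same moments, and the weighted logit-link projection.
At that scale the genotype-simulation curve stays within 0.02 of the closed
form everywhere, the oligogenic scenario shows visibly larger deviation
than the polygenic one (its 39-SNP score is less normal), and the weighted
projection agrees to floating-point precision.

What the simulations do *not* emulate: linkage disequilibrium between SNPs
(real panels are LD-pruned before scoring, and residual LD would inflate
the score variance), age structure, genotyping error or missingness, and
ascertainment bias in case recruitment. Passing validation therefore shows
the *mathematics* is right under the model's assumptions, not that any
particular real PRS satisfies them.

## Design choices

* The overall-population mixture at the overall K always defines the
  standardised axis, including for genotype-stratified runs, so stratified
  and unstratified curves are plotted against the same x.
* The stratified-curve prevalence condition (K = 0.10, ε4-like f = 0.18,
  OR = 3.2) mirrors the 65+ Alzheimer's setting used throughout the
  examples; age strata are handled by the caller supplying different
  (K, f) pairs, with no internal age model.
* Three-allele APOE genotypes and the protective ε2 allele are not
  modelled; the treatment is biallelic risk-allele only. Excluding the APOE
  region from the PRS loses the ε2 signal, which is why the no-variant
  curve can sit slightly above the non-carrier stratified curve.
* Property tests for the stratification identities draw parameters from
  K ∈ (0.01, 0.15), f ∈ (0.05, 0.4), OR ∈ (1.05, 3.5) — the region where
  the HWE-in-non-cases approximation keeps all three genotype prevalences
  inside [0,1]; outside it the model raises by design.
* The full-scale validation and Monte-Carlo parameter-recovery checks use
  10,000+10,000 genotyped individuals and 100,000 score draws per group
  respectively; these sizes make Monte-Carlo error comfortably smaller than
  the tolerances being checked while keeping the test suite fast.

## Known limitations

* Everything rests on summary moments; biased or mis-specified reference
  moments propagate directly into the curve. The curve's discriminative
  power is entirely inherited from the SNP selection behind the supplied
  moments.
* The equal-moments-across-strata assumption for high-effect variants is an
  approximation supported for APOE but not guaranteed for other loci.
* No confidence intervals are produced for α, β: the inputs are treated as
  known constants.
* Prevalence adjustment for sex, education or other non-genetic factors is
  possible in principle (by supplying stratum-specific K) but no interface
  is provided for it.
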