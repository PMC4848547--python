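# Methods

## The model

For each binary phenotype the package fits the standard GREML linear mixed
model on the observed 0/1 scale,

    y = Xβ + Σ_c g_c + e,     g_c ~ N(0, σ²_c A_c),   e ~ N(0, σ²_e I),

where each `A_c` is a genetic relationship matrix (GRM) computed from a
subset of SNPs (all SNPs; the HLA window chr6:26–34 Mb and its complement;
or the four-way MHC class I / class II / other-HLA / non-HLA split). This
is the "GLMM" of the GCTA lineage: the binary trait is analysed by a
*linear* mixed model and the variance ratio is transformed afterwards; no
logistic GLMM is attempted, because the transformation step is explicit
and the linear treatment is what the established toolchain does.

Estimation is restricted maximum likelihood with average-information (AI)
updates and EM-REML fallback. The restricted log-likelihood uses the
Harville form (it includes the −log|X'X| term), which makes the reported
value invariant to affine reparameterization of the covariate columns;
likelihood-ratio statistics are unaffected since both models share X.

Key numerical choices:

- **Unconstrained by default.** Variance components may go negative as
  long as V stays positive definite; this is deliberate (negative
  estimates of null phenotypes are diagnostic information, and constraints
  bias small-sample screens upward). `constrain_nonnegative=True` gives a
  projected variant with components clamped at a tiny floor.
- **Starting values.** Each genetic component starts at 0.25·Vp divided by
  the number of genetic components; the residual takes the remainder.
- **Step control.** A full AI step is tried first; if it leaves the
  feasible region (V not positive definite) or decreases the restricted
  likelihood, the step is halved up to 16 times, then an EM-REML step
  (σ²_i ← σ²_i + 2σ⁴_i·score_i/n) is used, itself shrunk toward the
  current point if needed. Convergence is |ΔlogL| < 1e-8 (configurable),
  with a cap of 100 iterations; hitting the cap flags `converged=False`
  rather than raising.
- **Standard errors** come from the inverse AI matrix at convergence;
  variance ratios and the genetic correlation use the delta method. A
  near-singular AI matrix (as with a GRM proportional to the identity,
  where σ²_g and σ²_e are not separately identifiable) sets an
  `ai_singular` flag.
- **Single-GRM fast path.** With one GRM the solver works in the GRM's
  eigenbasis, making each iteration O(n·p²) after one eigendecomposition
  (cached on the `Grm` object); multi-component and bivariate models use
  dense Cholesky algebra, with all AI entries computed from matrix-vector
  products so the only O(n³) cost per iteration is factorizing V.

### Liability transformation

Observed-scale ratios are mapped to the liability scale with

    h²_liab = h²_obs · K²(1−K)² / (z²·P(1−P)),

K the population prevalence, P the sample case proportion, z = φ(Φ⁻¹(1−K)).
The transform is sign-preserving and exactly invertible. When no
population prevalence is supplied, K defaults to P (the within-cohort
proportion); both scales are always reported so the choice is visible.

### Tests

- LRT against the no-GRM null uses a plain χ²₁ reference by default,
  because the unconstrained estimator is not pinned to the boundary under
  the null; the 50:50 χ²₀/χ²₁ mixture is available via `mixture=True` for
  compatibility with constrained fits.
- Per-component Wald tests refer (estimate/se)² to χ²₁.
- The rG = 0 test refits the bivariate model with the genetic covariance
  component removed and compares restricted likelihoods (χ²₁).
- Benjamini-Hochberg q-values are computed by the step-up rule with
  monotonicity enforced; input order is preserved.

### Bivariate model

The two traits' phenotype vectors are stacked; the covariance is built
from block structure matrices sharing one GRM — per-trait genetic and
residual variances, a genetic covariance on the cross blocks, and a
residual covariance defined only on samples present in both cohorts
(dropped automatically when the cohorts are disjoint). rG may exceed ±1
numerically in unconstrained fits; it is reported as estimated and flagged
undefined only when a genetic variance estimate is non-positive.

## GRM construction details

- Sample allele frequencies of the counted (A1) allele are taken from the
  analysis dataset after QC, not a reference panel.
- Missing genotypes contribute zero to the numerator, and the per-pair
  denominator is the count of SNPs non-missing in both samples.
- The diagonal uses the same standardized cross-product formula as the
  off-diagonals rather than GCTA's inbreeding-adjusted diagonal; the two
  agree in expectation under HWE and nothing downstream depends on the
  distinction.
- The Hardy-Weinberg filter is a Wigginton-style exact test (no mid-P),
  deterministic and verified against an exact-rational enumeration oracle
  for every table with up to 50 samples.
- Relatedness pruning is greedy: repeatedly remove the sample involved in
  the most over-threshold pairs (ties: higher missingness, then the
  lexicographically larger id). The default cutoff is 0.07 — appropriate
  for sparse, highly selected SNP panels where the conventional 0.025
  threshold removes nearly everyone — with 0.025 available by argument.
- LD r² is the squared Pearson correlation of dosage vectors (composite
  genotype r²; no phasing), computed over samples non-missing at both SNPs,
  on all QC-passing samples.

## The simulator

`simulate_genotypes` draws unlinked SNPs with ancestral MAF uniform on
[0.01, 0.5] (Balding-Nichols beta differentiation across subpopulations
when `fst > 0`), places 6.3% of SNPs evenly across an HLA window on
chromosome 6 (26–34 Mb) — matching the HLA density of an immune-enriched
exome array — and attaches sex, birth-decade and age metadata.
`default_hla_regions()` adds synthetic MHC class I and class II
sub-windows sized to give class SNP counts a few percent of the HLA block.

`simulate_liability_phenotype` draws causal effects on standardized
genotypes with per-region variance `h²_share/n_causal`, adds N(0, 1−h²)
environment, and thresholds the unit-variance liability at Φ⁻¹(1−K);
the truth record stores nominal and *realized* per-region variances.
`simulate_bivariate` uses shared causal SNPs with bivariate-normal effect
pairs, so `rho_effects` is the true rG. Control sampling matches the
(sex, birth-decade) case distribution at a 2:1 ratio, borrowing from the
nearest decade of the same sex when a stratum is exhausted.

All randomness fans out from one master seed into named substreams
(frequencies, genotypes, effects, environment, sampling), so any stage can
be re-run independently and outputs are byte-identical under a fixed seed.

What the simulator does **not** emulate: linkage disequilibrium beyond
structure-induced correlation, haplotypes, imputation error, EHR coding
dynamics over calendar time, and phenotype misclassification. Passing
recovery tests therefore demonstrates correctness of the estimators under
the liability-threshold model, not robustness to those real-data features.

## Problem sizes used in the shipped checks

Chosen to exercise each property at meaningful precision while keeping a
full run of the suite and the acceptance script to a few minutes each:

- univariate liability-h² recovery: population n = 3500, m = 5000 SNPs,
  K = 0.3, 500 causal SNPs, cohorts of ~3000 (all cases + 2:1 matched
  controls), h² ∈ {0, 0.2, 0.5};
- HLA/rest partition: n = 1800, m = 4000 (252 HLA SNPs), equal true
  shares of 0.3;
- bivariate rG: n = 1000, m = 3000, h² = 0.6 per trait, rho ∈ {0, 0.5};
- null calibration: 60 null phenotypes at n = 1000, m = 2500.

Recovery checks assert agreement within two (delta-method) standard
errors; calibration checks assert a near-zero median with a substantial
negative fraction, Kolmogorov-Smirnov uniformity of P-values, and BH flag
rates at or below the nominal FDR within binomial tolerance.

## Meta-analysis

Study rows printed as OR with a 95% CI are converted to log-odds with
SE = (ln CI_high − ln CI_low)/(2·z₀.₉₇₅) and pooled with fixed-effect
inverse-variance weights. Fixed-effect (not random-effects) pooling is
the package's choice: with two to three cohorts per SNP, between-study
variance is not estimable, and the fixed-effect pooled values reproduce
the published combined rows exactly at printed precision.

## Known limitations

- Case-control ascertainment is handled only through the K/P liability
  correction, which is approximate under strong ascertainment with large
  h²; no exact ascertainment-corrected likelihood is implemented.
- The bivariate solver is dense (O(n³) per iteration on the stacked
  system), practical to a few thousand samples per trait.
- No X-chromosome model, no dominance, no LD-aware SNP pruning for PCA.
- The four-GRM class model inherits the usual fragility of small variance
  components: with few SNPs per class the AI matrix can be ill-conditioned
  and non-convergence is reported per phenotype rather than repaired.
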