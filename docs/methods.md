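# Methods

This note documents the statistical model behind `mrmediate`, the choices
made where the design was genuinely open, what the synthetic-data generator
does and does not emulate, and known limitations.

## Model and assumptions

The package implements two-sample summary-data Mendelian randomization.
Genetic variants serve as instruments for an exposure under the usual IV
assumptions: association with the exposure, independence from
exposure–outcome confounders, and no effect on the outcome except through
the exposure (and, in the mediation setting, the modeled mediators).
Binary traits carry log-odds betas throughout; odds ratios are derived
views (`exp(beta)`), never stored. All analyses assume linear,
no-interaction effects on the log-odds/SD scales.

The two-stage workflow:

1. **Stage 1.** Univariable MR estimates the total effect of the exposure
   on the outcome, with MR-Egger, weighted median, weighted mode,
   MR-PRESSO, Cochran's Q, the Egger intercept and leave-one-out analysis
   as the sensitivity battery. Pairwise multivariable MR then re-estimates
   the exposure's effect conditional on each covariate trait in turn
   (joint models with several covariates are supported; pairwise is the
   default reporting layout).
2. **Stage 2.** For each candidate mediator: β₁ = exposure → mediator
   (UVMR), β₂ = mediator → outcome adjusted for the exposure (MVMR on the
   union of both traits' instruments). Mediators must pass a Bonferroni
   screen (p < 0.05/k in *both* steps, k = number of candidates; 0.01 for
   the five-lipid layout) before composition. Indirect effect = β₁β₂;
   proportion mediated = β₁β₂ / total.

## Estimator details and numerical choices

- **Wald ratios.** θ̂ⱼ = β_Yⱼ/β_Xⱼ with first-order SE se_Yⱼ/|β_Xⱼ|.
  SNPs with β_Xⱼ = 0 are dropped with a logged reason. The first-order SE
  neglects the exposure-side sampling noise; see "coverage" below.
- **IVW.** Fixed-effect SE (Σw)^(−1/2); the default multiplicative
  random-effects model scales it by max(1, √(Q/(m−1))), so the SE is never
  deflated below the fixed-effect value. This identity — IVW equals the
  zero-intercept weighted regression of β_Y on β_X with weights 1/se_Y² —
  is enforced by an oracle test against an independent WLS implementation.
- **MR-Egger.** SNPs are oriented so β_X ≥ 0 (rows flipped as a unit, which
  leaves slopes invariant and gives the intercept its directional meaning);
  weighted regression with intercept, weights 1/se_Y²; SEs carry
  max(1, residual SD). P-values are normal by default (t with m−2 df by
  flag), matching the normal convention used by every other estimator here.
- **Weighted median.** Standardized cumulative weights pⱼ = (Sⱼ − wⱼ/2)/Sₘ,
  linear interpolation at 0.5. SE by parametric bootstrap: β_X and β_Y are
  resampled from their sampling normals (default 5,000 draws, seeded,
  bit-reproducible).
- **Weighted mode.** Weighted normal-kernel density over the ratios with a
  Silverman-type bandwidth 0.9·min(sd, IQR/1.34)·m^(−1/5) times a
  user-visible `bandwidth_factor` (default 1); the estimate is the argmax on
  a 512-point grid spanning the ratios ±3 bandwidths. Zero spread returns
  the common value with the inverse-variance SE. Bootstrap SE as for the
  median.
- **MR-PRESSO.** Leave-one-out IVW slopes define observed weighted residuals
  RSSⱼ = wⱼ(β_Yⱼ − θ̂₍₋ⱼ₎β_Xⱼ)², wⱼ = 1/se_Yⱼ². K simulated datasets
  (default 1,000) draw β* from the sampling normals around the
  no-pleiotropy expectation; empirical p-values use the add-one estimator
  (1 + #exceedances)/(K+1), hence are bounded below by 1/(K+1). Outliers:
  per-SNP empirical p, Bonferroni-multiplied by m, compared to α = 0.05.
  The distortion test resamples pseudo-outliers from the non-outliers (500
  draws). The outlier-corrected estimate is reported alongside, never
  silently substituted for the primary IVW.
- **MVMR.** No-intercept WLS of β_Y on the m×k exposure-beta matrix with
  weights 1/se_Y², solved by least squares on the weighted design; a
  condition number above 1e8 raises an error naming it. SEs carry
  max(1, √(Q/(m−k))). MV-IVW with k = 1 reproduces IVW to machine
  precision, and MVMR-Egger reproduces MR-Egger (both identities are
  tested; the univariable Egger goes through statsmodels, the multivariable
  path through explicit normal equations, so the identity is a genuine
  cross-check).
- **Mediation algebra.** se(β₁β₂) = √(β₂²se₁² + β₁²se₂²);
  se(prop) = √((se_ind/total)² + (ind·se_tot/total²)²) — the ratio delta
  form written without dividing by the indirect effect so it is stable as
  the indirect effect approaches zero. Cross-covariances are set to zero:
  the two-sample, non-overlapping-cohorts assumption, stated rather than
  estimated. Proportions may fall outside [0, 1] (opposing paths, sampling
  noise); they are reported as computed with a RuntimeWarning. CIs are
  estimate ± 1.96·SE everywhere (normal 97.5% quantile).
- **Harmonization.** Outcome records are flipped to the exposure's effect
  allele where the labels are swapped; allele pairs matching neither
  orientation are dropped as incompatible. Palindromic SNPs: `strict` mode
  drops them all; the default `infer` mode drops them when either EAF is
  missing or within ±0.08 of 0.5, and otherwise uses the frequencies to
  detect strand flips. The ±0.08 window is the field's common default.
- **Clumping.** Greedy: visit candidates by ascending p (ties broken by
  snp_id for determinism), keep a SNP iff it has r² < threshold with every
  kept SNP on the same chromosome within the window (center-to-center kb).
  Pairs absent from the LD table are unlinked; LD is always an explicit
  input, never computed from genotypes. Note the retained set is *not*
  monotone in the r² threshold — a low threshold can exclude a SNP whose
  own exclusions would have pruned others — so only the independence
  property is guaranteed, and the implementation is verified against a
  brute-force reference on randomized instances.
- **Instrument strength.** Per-SNP Wald F = (β_X/se_X)², mean reported;
  mean F < 10 raises the weak-instrument flag. The Wald form is computable
  from summary statistics alone, unlike r²-based N-dependent formulas.

## The synthetic-data generator

Summary statistics are simulated directly on the beta/SE scale; two-sample
MR never consumes genotypes, so nothing is lost by skipping individual-level
simulation and the suite stays desk-scale. Per SNP and trait, the observed
beta is the true effect plus Normal(0, se) noise with

- continuous traits: se = 1/√(2p(1−p)·N),
- binary traits: se = 1/√(2p(1−p)·N·φ(1−φ)), φ = case fraction,

p = effect-allele frequency (uniform on (0.05, 0.95)), and p-values from the
Wald z. Each exposure instrument j has true effect bⱼ drawn as zⱼ·se_Xⱼ with
zⱼ ~ Normal(6.7, 0.8) and random sign, so the expected true Wald F is ≈ 46;
mediators and covariates receive α·bⱼ from the exposure path plus their own
instruments, and the outcome receives τ_direct·bⱼ plus every mediated path,
which makes the exposure-instrument outcome effect exactly τ_total·bⱼ.
τ_direct is always τ_total minus the sum of mediated paths (the linear
no-interaction identity, enforced by construction and test).

Features included to exercise the pipeline: LD partner SNPs per exposure
locus (r² = 0.9, tagging effect √r²·b, *correlated* sampling noise with
correlation √r² — independent noise would overstate the best-p-per-locus
winner's curse relative to real summary data); null SNPs; random allele-label
flips between tables; optional palindromic and incompatible-allele
corruption; and pleiotropy modes `balanced` (zero-mean), `directional`
(mean = magnitude, InSIDE-compatible) and `outlier` (offset of
magnitude × outcome-SE on a chosen fraction of loci, with the affected SNPs
recorded for recovery tests).

The bundled scenario fixes the study conditions: exposure 5,530 cases /
8,318 controls; five lipid mediators at N = 393k–441k; covariates adult BMI
(N = 339,224), WC (231,353), WHR (212,244); binary outcome 11,279 cases of
190,879. Effect sizes are the emulated study's point estimates
(α = −0.02, −0.04, 0.02, −0.04, 0.00733; γ = −0.13, −0.27, 0.26, −0.29,
−0.13; τ_total = ln 1.21), with covariate paths sized so the pairwise
adjusted direct effects equal ln 1.17, ln 1.10 and ln 1.21. Instrument
counts — 12 exposure loci, 200 per lipid, 70/40/30 per covariate — are
realistic for GWAS of these sample sizes and give step-1/step-2 standard
errors comparable to the emulated study's tables.

What the generator does **not** emulate: sample overlap between cohorts;
LD-aware effect correlation beyond the per-locus tag SNPs; population
stratification; allele-frequency differences between cohorts beyond small
noise; non-linear or interacting effects; measurement heterogeneity across
contributing studies. Passing tests therefore demonstrate correctness of
the estimators and pipeline under a clean two-sample design, not robustness
to those real-data pathologies.

## Calibration and coverage facts worth knowing

- With selection at p < 5×10⁻⁸ and mean instrument z ≈ 6.7, same-GWAS
  selection-and-estimation induces a winner's-curse attenuation of roughly
  4% on downstream causal estimates (bias ≈ 0.3–0.5 empirical SDs at the
  bundled sample sizes). Real analyses of this design inherit the same
  property. 95% CI coverage of the generating effects sits near 0.90–0.96
  in the recovery tests, not exactly 0.95.
- The reported mean Wald F among *selected* instruments (~55–65) exceeds
  the true-effect design value (~46) for the same reason: F is computed
  from observed, selection-inflated betas.
- The first-order Wald-ratio SE is accurate when θ²se_X² ≪ se_Y²; at weak
  instruments the multiplicative random-effects inflation absorbs most,
  but not all, of the neglected exposure-side variance.
- Empirical p-values from MR-PRESSO are uniform under the null to the
  resolution of a KS test at 200 replicates; per-SNP outlier tests are
  Bonferroni-conservative by design.

## Problem sizes used by the test and acceptance runs

Null calibration uses 1,000 replicates (m = 50 instruments); PRESSO
uniformity 200 replicates at K = 1,000; parameter recovery 200 replicates of
the full bundled scenario; outlier recovery 100 replicates; the clumping
oracle 1,000 randomized instances of ≤10 SNPs. The acceptance script
averages 20 full pipeline replicates. These sizes give Monte-Carlo error
comfortably inside every asserted band while keeping a laptop-scale run.

## Limitations

- No conditional F-statistics or Q-strength diagnostics for MVMR
  instrument strength (future work; the univariable mean F is reported).
- Proxy substitution consumes a user-supplied proxy map with an allele-phase
  column; there is no reference-panel lookup, strand inference from genome
  builds, or GWAS-VCF/liftover support.
- Steiger filtering, MR-RAPS, contamination-mixture and debiased IVW
  estimators, non-linear MR and multiple-mediator joint decomposition are
  out of scope.
- The mediation delta method ignores covariance between the total and
  indirect effects; with overlapping samples both β₁β₂ and the proportion
  SE would be optimistic.
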