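# Methods

This note records the statistical models the package implements, the
synthetic-data generator's assumptions, the defaults and why they were
chosen, and the numerical conventions a maintainer needs.

## Association models

**Disease.** Case–control status is modelled by unconditional logistic
regression with the per-allele (1-df) trend parameterization: the
effect-allele dosage (0–2, fractional dosages accepted) enters as a single
linear term alongside any covariates. Fitting is IRLS (statsmodels GLM,
binomial family) with gradient tolerance 1e-8 and at most 25 iterations.
Wald tests are used throughout; score and likelihood-ratio variants are not
implemented. Non-convergence and quasi-separation produce a *flagged* result
(NaN effect, `converged=False`) rather than an exception, so a region scan
never aborts on one pathological variant; a dosage column collinear with the
rest of the design (e.g. a perfect LD proxy of the conditioning SNP) is
flagged the same way. All-case or all-control input is a hard error.

**Hormones.** ln-scale hormone outcomes (ln E2, ln T, or their difference
ln E2 − ln T, which proxies aromatase activity by correcting for substrate)
are fitted by OLS. With `robust="cluster"` the clustered sandwich estimator
(X′X)⁻¹(Σ_g X_g′e_g e_g′X_g)(X′X)⁻¹ is applied over `cluster_id` groups with
the small-sample factor G/(G−1)·(n−1)/(n−k); with every cluster a singleton
this reduces exactly to HC1. This is the supported correction for family
designs (a kinship-matrix mixed model is intentionally out of scope — the
sandwich is the standard alternative when no kinship matrix is available).

**Missing data** are handled complete-case per variant per model — the
simplest deterministic convention; no imputation-quality filtering is done,
since dosages are accepted as-is.

## Meta-analysis

Fixed-effects inverse-variance pooling: weights wᵢ = 1/seᵢ²; pooled
β = Σwβ/Σw, se = (Σw)^(−1/2); Q = Σw(βᵢ−β)² on k−1 df; I² = max(0, (Q−df)/Q)
·100 (floored at zero, the standard definition); P_het from χ²(k−1).
Variants with P_het < 0.05 are excluded from downstream stages. For a
single usable study the pooled result equals that study with Q = 0 and P_het
undefined; such variants are retained with a warning rather than excluded,
because one-panel variants would otherwise silently vanish. The module pools
whatever per-study results it is given and does not require every study to
have typed every variant.

## Fine-mapping

The lead SNP is the retained variant with the smallest pooled P (ties: the
larger Wald χ², then the lowest genomic position). The conditional scan
refits each remaining variant with the lead dosage appended to the covariate
block — a genotype-level conditional analysis, not a summary-statistic
approximation — and declares a second independent signal iff any conditional
P ≤ 10⁻⁴. The candidate causal set operationalizes "likelihood ratio better
than 1:100 against the top SNP" through the asymptotic summary-statistic
form LRᵢ = exp((χ²_lead − χ²ᵢ)/2) with χ² = (β/se)², combined with the hard
LD filter r² > 0.2; r² is the squared Pearson correlation of dosages
(composite LD), which is what imputed data permit — no phasing is assumed.

## Quartile stratification and interaction

Quartile cutpoints are the 25/50/75 empirical percentiles (linear
interpolation) of the variable's distribution *in cases*, which balances
case counts — hence power — across strata; the same cutpoints are reused for
the hormone analysis so both phenotypes are stratified comparably.
Assignment intervals are left-closed/right-open with the top interval closed
below ("<c₁", …, "≥c₃"). Disease analyses within BMI strata adjust for age;
hormone analyses in strata use ln E2 uncorrected for T (maximizing sample
size). The interaction test is a single joint model with main effects
(dosage, quartile index 0–3 treated as ordinal, covariates) plus a
dosage × index product term, tested by a 1-df Wald test. The ordinal product
term was chosen over a 3-df categorical interaction because the scientific
question is a monotone dose-modification trend, summarized by one P value;
the P is invariant to affine relabeling of the index. Strata smaller than 50
samples (configurable) are refused.

## Wald-ratio Mendelian randomization

The instrument's effect on the exposure is the per-allele slope β on
ln E2; the exposure–disease link is an external OR per *doubling* of E2
(defaults: endometrial 2.06, CI 1.47–2.89; breast 1.29, CI 1.15–1.44). The
predicted per-allele disease OR is exp(ln(OR_doubling)·β/ln 2): an allele
multiplying E2 by e^β covers β/ln 2 of a doubling on the log₂ scale, so an
allele that exactly doubles E2 (β = ln 2) inherits the full per-doubling OR.
The prediction interval uses the delta method on the log OR treating the two
sources as independent:

var(ln OR_pred) = (β/ln 2)²·var(ln OR_doubling) + (ln OR_doubling/ln 2)²·se_β²,

with var(ln OR_doubling) recovered from the published CI under a symmetric
95% Wald interval on the log scale — the external source rarely states its
variance, and this recovery is exact when the published interval is
log-symmetric (published intervals that are not exactly log-symmetric
introduce a small, conservative approximation). Observed and predicted ORs
are compared by z = (ln OR_obs − ln OR_pred)/√(se_obs² + se_pred²);
"compatible" means two-sided P ≥ 0.05. Ancillary quantities: the percent
effect per allele 100·(e^β − 1) with CI from the endpoints, and the variance
explained 100·2f(1−f)β²/var(phenotype) under HWE.

## Synthetic-data generator

The generator emulates the *statistical structure* the analysis assumes, at
the study's scale, so every stage is testable without real data. Defaults
(one place, `SimulationConfig`):

| parameter | default | rationale |
|---|---|---|
| studies (cases/controls) | (4402/28 758), (925/6225), (667/1288), (614/1654) | four studies totalling 6608/37 925, dominated by one large array study |
| control effect-allele freq | 0.651 | study-scale control frequency of the lead allele |
| per-allele disease OR | 1.15 | generating disease effect |
| hormone cohort | n = 2767, f = 0.656 | hormone-arm size and frequency |
| β on ln E2 / ln T | 0.096 / −0.045 | generating hormone effects |
| residual SD of ln E2 | 0.64 | makes the slope SE ≈ 0.018 at n = 2767 and f = 0.656 (se = sd/√(2nf(1−f))); the true residual variance of ln E2 is not published, so this is a free parameter calibrated to the reported precision |
| adjacent-marker r² | 0.6 (0.99 available for proxy studies) | enough LD to exercise r² filtering and conditional scans |
| BMI quartile cutpoints | 24.3 / 28.0 / 33.2 kg/m² (ages 57/63/69) | the case-distribution stratum boundaries the stratified analyses use |
| BMI means (case/ctrl) | 28.8 (SD 6.5) / 25.8 (SD 4.8), truncated normal | cases heavier than controls, so control counts thin toward high-BMI strata while case quartiles stay balanced |

**Haplotypes** follow a first-order Markov chain along position-ordered
variants: marginal frequencies are preserved exactly in expectation and each
adjacent pair targets correlation √r² (optionally decayed exponentially with
inter-marker distance). Conditional probabilities leaving [0,1] — which
happens for strongly mismatched adjacent frequencies at high target
correlation — raise a parameterization error rather than being clipped.
This is deliberately *not* a coalescent: recombination hot-spots, allele-age
structure and long-range LD are absent, so passing tests say nothing about
those features of real data; they do exercise everything downstream of a
dosage matrix with tunable local LD.

**Case–control sampling** is retrospective under the rare-disease
multiplicative model: controls are random haplotype pairs from the pool;
for cases the causal-genotype class g is drawn with probability
∝ P_HWE(g)·exp(b·g) and haplotypes are then drawn from the matching
causal-allele strata, preserving the pool's LD conditional on the causal
site. This is exact for the per-allele logistic target and orders of
magnitude faster than prospective simulation at a realistic disease rate.
A per-subject b = log OR + interaction_coef × (BMI quartile) generates
gene–environment interaction.

**Hormone cohorts**: ln E2 = intercept + β·dosage + age/BMI/HRT/menopause
terms + batch and study effects + optional shared family-cluster effect +
Gaussian noise; ln T likewise. The covariate coefficients are small
plausible values; they exist to give the adjustment machinery something to
adjust for, not to match any particular population.

**Causal-chain generator** (`simulate_disease_through_e2`): genotype → ln E2
→ disease, with retrospective case weights exp(γ·ln E2), γ =
ln(OR_doubling)/ln 2. The Gaussian noise factors out of the weights, so the
induced marginal per-allele log-OR is exactly γ·β — making "observed agrees
with Wald-ratio prediction" a sharp end-to-end correctness statement, tested
over 100 replicates at full study scale. E2 is recorded for controls only,
mirroring designs where hormones are measured in healthy women.

**Randomness**: a single mandatory integer seed; every stage draws from a
deterministic child stream (`SeedSequence(entropy=seed, spawn_key=...)`), so
stages are independently reproducible and a fixed seed gives byte-identical
output files.

## Numerical conventions and edge cases

- Two-sided Wald P values from the normal approximation, floored at the
  smallest positive double to avoid literal zeros in output.
- 95% CIs use 1.96 throughout.
- Dosages outside [0,2] are rejected at I/O and container boundaries;
  missingness is an explicit mask, not a sentinel value.
- Monomorphic variants: r² and allele frequency return NaN with a warning.
- VCF: DS takes precedence over GT when both are present; multi-allelic
  records are skipped with a warning; variants are position-sorted on read;
  written dosages carry 3 decimals (round-trip tolerance 5e-4).
- Percentiles use numpy's linear interpolation; any deterministic rule would
  do, and cutpoints derived from synthetic cases are only loosely comparable
  to published boundary values.

## Problem sizes used in the test suite

Stochastic checks run at the sizes stated above where the claim is about the
study scale (pooled-OR recovery, hormone-slope recovery, the 100-replicate
MR consistency loop) and at reduced sizes for calibration loops where only
the null behaviour matters (type-I error of the interaction test at n = 1500
over 120 replicates; meta-analysis calibration over 200 synthetic 4-study
draws; bias check of the hormone generator at n = 800 over 40 replicates).
These reductions are the package's own choice of test economy; the
acceptance script always runs at full study scale.

## Known limitations

- The LD model is locally Markov; summary-statistic fine-mapping methods
  that rely on realistic long-range LD patterns should not be benchmarked
  against it.
- The Wald ratio uses a single instrument; pleiotropy-robust multi-variant
  MR estimators (median, Egger) are out of scope.
- The heterogeneity exclusion is a hard pre-filter, as specified, not a
  random-effects alternative.
- Sample overlap between the case–control and hormone arms is ignored by
  the independence assumption of the prediction CI (in the emulated design
  the hormone arm is controls only, so the induced correlation is small).
- The compatibility test can fail to reject simply because the prediction
  interval is wide; "compatible" is evidence of consistency, not proof of
  causality.
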