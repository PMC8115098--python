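# Methods

This note documents the statistical procedures implemented in `mrkit`,
the assumptions behind them, the defaults and why they were chosen,
what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Two-sample MR model

Each instrument j contributes marginal associations (β̂_Xj, se_Xj) from
the exposure GWAS and (β̂_Yj, se_Yj) from a non-overlapping outcome
GWAS.  Under IV1–IV3 the Wald ratio β̂_Yj/β̂_Xj estimates the causal
effect β of one exposure unit on the outcome (log-odds for binary
outcomes).  Estimators:

- **IVW** — weighted mean of the ratios with first-order weights
  w_j = β̂_Xj²/se_Yj².  Default is multiplicative random effects: the
  fixed-effects SE (Σw)^(−1/2) is inflated by max(1, √(Q/(k−1)));
  the floor at 1 means the SE never drops below fixed effects.
  Minimum 2 instruments.
- **MR-Egger** — weighted regression of β̂_Y on β̂_X with intercept,
  weights 1/se_Y², after flipping instruments to non-negative β̂_X
  (required for the intercept to mean "average directional
  pleiotropy").  The regression is a statsmodels WLS fit; its
  covariance scale Q/(k−2) gets the same floor of 1.  Validity needs
  InSIDE plus the no-measurement-error (NOME) condition, monitored by
  I²_GX = max(0, (Q_GX − (k−1))/Q_GX) on the exposure effects; the
  pipeline warns when I²_GX ≤ 0.9.  Minimum 3 instruments.
- **Weighted median** — weighted 50th percentile of ratios (linear
  interpolation of cumulative normalized weights at 0.5), weights
  1/se_ratio² with second-order delta-method ratio SEs
  se_ratio² = se_Y²/β̂_X² + β̂_Y²se_X²/β̂_X⁴.  Consistent when ≥50% of
  weight comes from valid instruments.  SE by seeded parametric
  bootstrap (default 1000 draws) resampling both effect sides.
- **Weighted mode** — maximiser of a Gaussian-kernel weighted density
  over ratios; bandwidth is the modified Silverman rule
  0.9·min(sd, mad)·k^(−1/5) times a user factor (default 1), density
  maximised on a 512-point grid spanning the ratios ±3 bandwidths.
  Consistent when the largest cluster of ratios is valid ("plurality
  valid").  Degenerate zero bandwidth falls back to the heaviest point
  mass.
- **MR-PRESSO** — observed global RSS = Σ_j (β̂_Yj − β̂_Xj·β̂_(−j))²/se_Yj²
  with β̂_(−j) the leave-one-out IVW estimate; the null distribution is
  simulated (default 1000 draws) by redrawing both effect sides from
  their sampling distributions around the leave-one-out predictions.
  Global p = exceedance fraction with the (r+1)/(n+1) correction;
  per-instrument outlier p-values come from each instrument's
  simulated residual distribution, Bonferroni-corrected over k, flagged
  at 0.05.  The returned fit is the outlier-corrected IVW.  The
  distortion test is not implemented.  Requires ≥4 instruments and
  n_sim ≥ k/α so the requested outlier level is resolvable.
- **Correlated-instrument IVW** — generalised least squares with
  Ω_ij = ρ_ij·se_Yi·se_Yj from a signed LD correlation matrix; with
  identity LD it equals fixed-effects IVW exactly.  Positive
  semi-definite Ω is accepted via pseudo-inverse, which collapses
  perfectly correlated duplicate instruments to a single one;
  indefinite input is an error.  This is a technical replication of
  IVW under correlated instruments, not a re-implementation of any
  specific published estimator.

All p-values are two-sided from the normal distribution (summary-data
asymptotics).  With k around 14 the normal approximation makes the
Egger intercept test mildly liberal (the exact reference would be
t with k−2 df, ≈7% at nominal 5%); its calibration test therefore runs
at k = 50, where the approximation is accurate.

## Instruments

Selection keeps genome-wide significant variants (p < 5×10⁻⁸),
sorted by p with snp_id tie-breaks.  Clumping is greedy: keep the most
significant remaining variant, drop all others within 10,000 kb with
LD r² ≥ 0.001 (defaults match conventional two-sample-MR practice).
LD comes from a user-supplied matrix; with none supplied all pairs are
treated as independent, with a warning.  Harmonization aligns outcome
effects to the exposure's effect allele: label swaps flip the sign and
mirror the frequency; strand complements are accepted; palindromic
(A/T, C/G) variants are kept only when both allele frequencies are
outside [0.42, 0.58] (half-width 0.08) and on the same side of 0.5 —
discordant-side palindromes are removed rather than sign-flipped,
trading a little power for never orienting on a coin flip.  Exposure
instruments missing from the outcome are dropped (no proxy lookup);
non-complementary mismatches are marked removed, never silently
discarded.  Instrument strength: per-variant variance explained is
recovered from (p, n) by inverting the F(1, n−2) quantile
(r² = t²/(t²+n−2), with a χ²(1) fallback where the F inversion
overflows), summed over the set, and converted to
F = R²(N−k−1)/((1−R²)k).  F is always recomputed from inputs, never
copied from a published table.  Covariate-stability partitioning
(instruments significant with and without covariate adjustment) and
confounder-overlap removal (drop instruments genome-wide significant
for a confounder such as BMI) operate on snp_id sets.

## Sensitivity analyses

Cochran's Q uses the IVW weights about the IVW estimate, p from
χ²(k−1).  Under a nonzero causal effect and noisy exposure effects,
E[Q/(k−1)] exceeds 1 by roughly β²se_X²/se_Y² even without pleiotropy
(a NOME effect); the null-calibration test therefore simulates β = 0.
Leave-one-out refits IVW omitting each instrument and flags omissions
that move the estimate outside the full fit's 95% CI or change its
sign; because the full CI is heterogeneity-inflated, only
high-precision outliers can trigger the flag — the flag is a screen,
not a test.  The Steiger directionality test sums per-instrument
variance explained on both sides (binary outcomes converted to the
liability scale) and compares the implied correlations with an
independent-samples Fisher-z test; the pipeline runs it at both bounds
of the outcome's prevalence interval (anorexia-like outcomes default
to 0.9% and 4%).

Liability conversions: observed-scale variance explained becomes
r²·K²(1−K)²/(z²P(1−P)) (K prevalence, P sample case proportion, z the
standard-normal density at the liability threshold) — validated in the
tests against a direct threshold-model simulation, where it is exact
to ~1% unascertained and ~10–15% under strong case enrichment, a known
property of the first-order transformation.  A binary exposure's
log-odds-unit effect becomes an effect per SD of liability via the
factor z/(K(1−K)); this factor was adopted because it reproduces both
published converted estimates from their observed-scale inputs at the
stated prevalences.  Multiple testing: Bonferroni threshold α/m, or
Benjamini-Hochberg step-up (statsmodels); BH flags are always a
superset of Bonferroni flags at equal α.

## Latent causal variable model

For genome-wide munged z-scores of two traits, write normalized
per-SNP genetic effects as α_t = q_t·π + γ_t with a shared latent
factor π and trait-specific γ_t; the genetic correlation is ρ = q₁q₂
and the genetic causality proportion is defined by
q₁ = |ρ|^{(1−gcp)/2}, q₂ = |ρ|^{(1+gcp)/2}.  Because π is heavy-tailed
in real architectures, the noise-cancelling mixed fourth-moment
cumulants

    k41 = E[z₁³z₂] − 3·E[z₁²]·E[z₁z₂],
    k42 = E[z₁z₂³] − 3·E[z₂²]·E[z₁z₂]

satisfy K41/K42 = |ρ|^{−2·gcp} after scale normalization, so
T(x) = sign(ρ)·(K41·|ρ|^x − K42·|ρ|^{−x}) crosses zero at the true
GCP.  The estimator computes weighted moments (LDSC-style weights
1/max(1, ldscore)), evaluates T over the grid x ∈ [−1, 1] in steps of
0.01, attaches a delete-one block-jackknife SE to each T(x)
(100 contiguous SNP blocks by default), and reports the posterior mean
and SD of the grid under the t-likelihood of T(x)/SE(x), plus
two-sided t-tests of GCP = 0, +1, −1.  Estimates are exactly
antisymmetric under trait exchange.  Heritabilities are estimated from
the weighted mean of z² − 1 (scaled by M/(N·mean LD score)); a
non-positive estimate for either trait is a hard error naming the
trait.  Sample-overlap intercept correction is not applied (the
intended use is non-overlapping GWAS pairs).  SNPs flagged at munging
for χ² above the cap are retained unmodified.  |ρ| is clipped to
[0.01, 0.99] for numerical stability of |ρ|^x.  The `seed` parameter
is reserved; the estimator is deterministic.

## Synthetic data

`simulate_iv_dataset` draws n_iv instrument effects whose per-variant
variance explained is mildly heterogeneous (uniform ±30% around
R²/n_iv, normalized to sum to R²) plus background null SNPs; observed
effects add sampling noise with se = 1/√(2·maf(1−maf)·n) on both
sides; outcome effects are β·β_Xj(true) + α_j with pleiotropy α_j
drawn per model (balanced: mean-zero normal; directional: nonzero
mean, applied relative to the exposure-increasing allele so the Egger
intercept targets the mean; correlated: α_j ∝ |β_Xj| + noise,
violating InSIDE), optionally restricted to a fraction of instruments.
Defaults mirror the fasting-insulin design: 14 instruments, R² = 0.64%,
n_exp = 108,557, n_out = 72,515, β = −0.72.  A design whose mean
per-instrument noncentrality cannot reach genome-wide significance is
rejected with the minimal feasible R².  Allele frequencies are uniform
on [0.05, 0.5]; 10% of SNPs are palindromic and 10% of outcome rows
carry swapped allele labels, exercising every harmonization path.
Optional LD blocks give within-block effect and noise correlation r
and an emitted r² matrix.  `simulate_bmi_pair` pins instrument z-scores
above the significance threshold in the adjusted dataset and pins a
chosen fraction at z = 4 in the unadjusted one, so the
covariate-stable set is recovered exactly by construction.
`simulate_genomewide` uses sparse (point-normal) latent and direct
effects (5% and 20% causal density) to supply the excess kurtosis the
LCV estimator requires, with LD-free SNPs (all LD scores 1).

What the generator does **not** emulate: realistic human LD maps,
allele-frequency-dependent architectures, sample overlap,
ascertainment of instruments through discovery in the same data
(winner's curse), population stratification, or binary-outcome
link-scale subtleties (outcome effects are generated on a continuous
scale and interpreted as log-odds).  Passing tests therefore
demonstrate correctness of the estimators and pipeline logic under the
stated model, not robustness to those real-data features.

## Calibration test design

The IVW bias/coverage suite evaluates the estimator on the generator's
known instrument set rather than re-selecting by significance, so it
measures estimator properties (weak-instrument attenuation ≈ 1/F ≈ 2%
at the default design; observed ≈ 1.6%) without conflating them with
winner's curse, which selection adds (≈ +1.5% attenuation) and which
the recovery tests cover separately.  Strong-instrument configurations
(n_exp = 2×10⁶) are used where a procedure's validity conditions
require NOME — the Egger intercept tests, I²_GX > 0.9 checks, and the
correlated-IVW coverage test (plain GLS models outcome-side
correlation only).  Stochastic suites use fixed seeds and documented
problem sizes: 1000–2000 replicates for IVW calibration, 1000 null +
150 planted-outlier sets for MR-PRESSO, 20 genome-wide simulations of
20,000 SNPs for LCV sign recovery and 16 for its null.

## Known limitations

- No proxy-variant lookup, liftover, or reference-panel management;
  LD is always an explicit input.
- MR-PRESSO's distortion test, multivariable MR, and Egger-SIMEX are
  out of scope.
- The LCV weighting is a simple LDSC-style scheme; with strong LD
  heterogeneity the fourth-moment statistics would need LD-aware
  corrections the generator does not exercise.
- The pipeline's N/A rule (fewer than 3 usable instruments) and
  two-tier sensitivity gating (full suite at corrected significance,
  Egger/median/mode at nominal significance, a flag to force both) are
  fixed conventions, configurable but not adaptive.
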