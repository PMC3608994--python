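# Methods

## Model and assumptions

`platsem` fits a one-factor confirmatory measurement model. For subject
*s*, platform *i* reads a latent variable ξ_s (here: the true logit-scale
relative frequency of a bacterial taxon) as

    Y_is = λ_i ξ_s + ε_is,      ζ, ε independent, zero-mean normal,

with Var(ξ) = σ_ζ², Var(ε_i) = σ_{ε_i}², and one loading fixed at 1 (the
*reference indicator*, default: the first) to give the latent variable a
scale. All variables are centered, so only second moments matter: the
sufficient statistic is the sample covariance (or correlation) matrix plus
N, and every fitting routine accepts either raw data or that moment summary.

With covariates, the latent variable is regressed on observed X
(ξ = Γ′X + ζ) while still being measured by all platforms (a MIMIC-style
model). The covariate block of Σ(θ) is saturated — cov(X) is freely
estimated — so χ², RMSEA and CFI measure only the measurement/structural
restrictions, not the covariate distribution.

Key outputs per platform: the standardized loading λ*_i = λ_i σ_ξ/σ_{Y_i}
(the platform–latent correlation, computed from the *implied* variances) and
the reliability R²_i = 1 − σ_{ε_i}²/σ_{Y_i}² = (λ*_i)². A sample-variance
denominator is available as an option; the two coincide at any
just-identified optimum.

## Estimation

F_ML = log|Σ(θ)| + tr(SΣ(θ)⁻¹) − log|S| − p is minimized over an
unconstrained reparameterization: free loadings and Γ as-is, log σ_ζ²,
log σ_{ε_i}² (a single log σ_ε² under the univariate-ANOVA constraint), and
a Cholesky factor with log-diagonal for cov(X). BFGS with gradient
tolerance 1e−9 and up to 5 deterministically jittered restarts; failure
after restarts raises an error carrying the best value and gradient norm.
Start values: λ_i from S_{i,ref}/S_{ref,ref}, σ_ζ² at half the reference
variance, error variances at half the indicator variances, Γ from the OLS
regression of the reference indicator on X.

The just-identified three-indicator FREE model is solved in closed form
(λ̂₂ = S₂₃/S₁₃, λ̂₃ = S₂₃/S₁₂, σ̂_ζ² = S₁₂S₁₃/S₂₃, σ̂_{ε_i}² = S_ii −
σ̂_ζ²λ̂_i²) and only falls back to the optimizer when the closed form lands
in a Heywood region, so that reported variances respect the boundary.

χ² = (N−1)·F_ML by default (`n_convention="n-1"`, pairing with the N−1
covariance denominator; `"n"` is available). P-values use the χ²_df upper
tail; at df = 0 the p-value is undefined and reported as NaN.

**Heywood cases.** The log-parameterization keeps optimizer variances
positive; a fit is flagged `heywood` when any error variance falls below
1e−6 of its indicator variance. The closed-form path (and the closed-form
bootstrap replicates) may return literally negative error variances, i.e.
reliabilities above 1; these are reported raw with a flag and never
truncated — only bootstrap CI endpoints on the reliability scale are
clamped to [0, 1].

**Sign convention.** The latent variable is oriented so λ_ref = +1. A
sign-inconsistent off-diagonal pattern (negative triple product) is an
identification error whose message suggests reflecting an indicator; the
reflection is never applied silently.

**Standard errors.** Wald SEs come from the numerically inverted observed
information of (N−1)/2·F_ML at the optimum (finite-difference Hessian, via
statsmodels), computed over (λ, σ_ζ², σ_ε², Γ) with cov(X) held at its
estimate — exact for k = 0 since the X block is saturated. Covariate
p-values are two-sided normal. The bootstrap is the recommended
alternative whenever normality is in doubt; both are provided and neither
is privileged.

## Constrained (ANOVA-equivalent) models

`EQUAL_LOADINGS` fixes all λ_i ≡ 1 (multivariate repeated-measures ANOVA);
`EQUAL_LOADINGS_EQUAL_ERRORS` additionally imposes one common error
variance, implying compound symmetry (univariate ANOVA). Degrees of
freedom: p(p+1)/2 minus free parameters (2m for FREE at k = 0; m+1 and 2
for the constrained modes). The three models are nested, so F_ML is
non-decreasing down the ladder and `compare_models` reports adjacent
χ²-difference tests. Note the constrained modes are *not* scale invariant
(fixing λ = 1 is a statement about units); the FREE mode is, and fitting a
correlation matrix gives the same χ² as the covariance matrix there.

## Fit indices

RMSEA = √(max(χ²−df, 0)/(df(N−1))), defined as 0 for a saturated model.
CFI = 1 − d_model/d_null with d = max(χ²−df, 0), clamped to [0, 1]. The
baseline is the independence model Σ = diag(S), whose discrepancy reduces
to −log|R| (R the correlation form); df_null = p(p−1)/2. The independence
baseline is the conventional choice and reproduces the published CFI for
the four-platform fixture.

## Bootstrap

Efron's nonparametric bootstrap: subjects (rows) resampled with
replacement, n fixed, covariates traveling with their rows. All replicate
index sets come from one seeded generator drawn as a (B, n) block, so
replicate r is identical whatever B is. Replicates that fail (sign
inconsistency, non-convergence, degenerate resample) are dropped and
counted; above 20% failures the run errors out with the failure modes.
Intervals are percentile (2.5th/97.5th at the default level), using linear
interpolation of the empirical CDF (the type-7 quantile convention —
unstated in most applied work, so fixed and documented here).

For the three-indicator FREE model the replicates use the closed form
vectorized over all B resamples, which both makes B = 1000 essentially free
and reproduces the behaviour of classical SEM software whose replicate fits
can cross the Heywood boundary — the reason published reliability intervals
can have an upper endpoint of exactly 1.000.

## Transforms

Sequencing counts enter as the empirical logit log((k+c)/(n−k+c)) with the
Haldane–Anscombe smoothing constant c = 0.5 (configurable), finite at k = 0
and k = n. qPCR dCT values enter as logit(2^dCT), defined for dCT < 0.
`logit_effect_to_proportion_diff` converts a fitted Γ and covariate pattern
into logistic(Γ′x) − 0.5, the implied shift in the underlying proportion
against the centered baseline — an interpretation aid, not a marginal-effect
estimator, since it fixes the latent intercept at 0 on the centered scale.

## Synthetic data

The generator draws exactly the model's data-generating process: ζ normal,
ξ = Γ′x + ζ, Y = λξ + ε with independent normal errors (optionally scaled-t
with matched variance, to exercise the bootstrap under heavy tails), plus a
binomial count generator feeding the empirical logit. The default scenario
calibrates the truth to the packaged four-platform correlation fixture
(loadings ≈ (1, 1.02, 1.05, 0.73) on the correlation scale, latent variance
≈ 0.82, reliabilities (0.82, 0.86, 0.91, 0.44)) with the published
phenotype design (39 CD / 50 UC / 53 controls) and coefficients
(−0.592, −0.164) available on request — so simulations run at the study's
own regime. The generator does *not* emulate compositionality across taxa,
zero inflation, overdispersed counts, or platform-specific biases that act
multiplicatively on frequencies rather than linearly on logits; passing
recovery tests therefore validate the estimator under its own assumptions,
not robustness to real-data violations (the scaled-t option probes only the
error-tail assumption).

## Problem sizes and numerical choices in the test suite

Tests run the published four-platform fixture (N = 142) exactly; recovery
checks use 50 replicates of n = 10⁴ (bias), 1000 replicates of n = 142
(median reliability), and a bootstrap coverage study of 500 datasets at
n = 200 with B = 1000 replicates each — sizes chosen to bound Monte-Carlo
error well inside the asserted tolerances while keeping the suite around a
minute. Matrix positive-definiteness is decided by Cholesky; moment
matrices must be symmetric to 1e−12 (relative); optimizer agreement with
the closed form is asserted to 1e−6 in F_ML; elementwise Monte-Carlo
covariance checks use a 3.5-SE band to account for the ten simultaneous
comparisons.

## Known limitations

Single-factor models only (no multi-group or multi-factor structures);
ML/normal-theory estimation only (no GLS/WLS/ADF, no mean structures);
no robustification for rare taxa, whose near-zero counts produce unstable
logit variances; Wald SEs near a variance boundary are unreliable (use the
bootstrap); constrained-mode fits depend on measurement units by design.
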