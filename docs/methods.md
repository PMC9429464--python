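# Methods

## Model

The package treats psychiatric morbidity as a unidimensional latent factor
measured by the twelve GHQ-12 items. Each observed item `Y_pij` (coded 1–4,
higher = more morbidity under the standard Likert key; the responses are
already ordered toward morbidity, so no reverse-scoring step exists) is a
discretized continuous latent response

    Y*_pij = λ_p η_ij + ε_pij,   ε_pij ~ N(0, θ_p),
    Y_pij = c  ⇔  τ_p,c−1 < Y*_pij ≤ τ_p,c,

with strictly increasing thresholds τ on the latent-response scale. The
structural part is a two-level random-intercept factor model:

    η_j(HH)  = γ′Z_j + u_j,             u_j ~ N(0, ψ_HH)
    η_ij     = β′X_ij + η_j(HH) + e_ij,  e_ij ~ N(0, ψ_Ind)

The same loading vector serves both levels (cross-level invariance), and
λ_1 = 1 fixes the factor scale. Eight individual predictors enter β
(co-resident history of mental disorder, age in years, male, working,
personal history, householder, closeness to others 1–5, BMI) and two
household predictors enter γ (deprivation quintile, household closeness).

Key interpretable quantities: the latent intraclass correlation
ICC = ψ_HH/(ψ_HH+ψ_Ind) from the null (structural-baseline) model, and the
per-level explained variance (ψ_Null − ψ_Full)/ψ_Null.

## Estimation

**Stage 1 — limited information.** Item thresholds are inverse-normal
quantiles of cumulative category proportions. Pairwise polychoric
correlations use two-step maximum likelihood (thresholds fixed from the
margins, ρ maximizing the bivariate-normal cell-probability likelihood);
rectangle probabilities come from Owen's T function, which is exact and
vectorizes over cells. Estimates are clipped at |ρ| = 0.995 so downstream
weight matrices stay finite; a clipped estimate reports an infinite
asymptotic variance. Asymptotic variances (√n scale) come from the inverse
observed information and serve as the DWLS weights. Empty categories are
collapsed into their neighbour with a warning.

**Measurement model — DWLS.** The one-factor model with free error
covariances is fit by minimizing F = (s−σ(θ))′W⁻¹(s−σ(θ)) with W the
diagonal of the asymptotic variances, via Levenberg–Marquardt on the
weighted residuals with an analytic Jacobian. χ² = (n−1)·F̂ with no
mean/variance correction (plain DWLS; a robust correction could be layered
on the same discrepancy and is a known limitation). RMSEA uses n−1.
GFI is defined in the W-metric as 1 − F̂/F_baseline (the classic ML-GFI
is undefined for this estimator; the choice is declared in the report).
Standard errors use the sandwich form, which collapses to (Δ′W⁻¹Δ)⁻¹/(n−1)
because only the diagonal of the sampling covariance of s is estimated.
Modification indices are Gauss–Newton score statistics: the expected χ²
drop from freeing one fixed-to-zero error covariance, computed by
projecting its Jacobian column out of the span of the free parameters.
The stepwise procedure frees the largest-MI covariance while the largest
MI exceeds 3.84 (the χ²₁ 5% critical value — no stopping rule beyond
improved fit is prescribed elsewhere) and df > 0; it stops with a
saturation notice at df = 0. Freeing all 66 covariances would outstrip
the 66 sample statistics, so "all error covariances free" is reachable
only as this saturation limit.

**Structural model — full-information ML.** The household likelihood
integrates the household residual (outer Gauss–Hermite rule) and each
member's residual (inner rule), with the product over items of
ordinal-probit category probabilities inside. Gradients are computed
analytically alongside the value (posterior-weighted expectations of the
per-item derivative terms), so a survey-scale fit takes seconds and the
numerical Hessian for standard errors needs only ~2k gradient evaluations.
ψ parameters are optimized on the log scale to enforce non-negativity;
estimates below 10⁻⁶ are flagged as boundary solutions. AIC = −2ℓ+2k and
BIC = −2ℓ+k·log(N individuals) count only the parameters the ML stage
estimates (in two-stage mode the measurement parameters are fixed, so
they are not counted — these criteria compare structural candidates on
the same measurement, not measurement models).

Default mode is two-stage: loadings and thresholds fixed at the stage-1 /
DWLS estimates, with θ_p = 1 − λ_p²ψ̂ from the delta convention (floored
at 0.05 near Heywood cases, with a warning). Joint estimation of the
loadings is available behind a flag (`estimate_loadings=True`); thresholds
remain stage-1 in either mode. The ML backend supports a diagonal Θ only:
freed error covariances are a property of the measurement report, because
a full 12-dimensional correlated ordinal probit is intractable at desk
scale. The stated estimator of record for the original analysis was DWLS
throughout; a multilevel-categorical DWLS is not well defined from that
description, while the probability model is, so the structural stage uses
ML and says so in the report header.

**Centering and the latent intercept.** Predictors are centered before
optimization (conditioning) and a free latent intercept is estimated
whenever centering is on — in the null model too. The intercept absorbs
whatever latent mean the fixed thresholds do not already carry: for
stage-1 thresholds (estimated from the pooled margins, which absorb the
mean) it estimates ≈ 0; for generator-scale thresholds it estimates the
structural mean. Without it, a location mismatch would leak into the
variance components. Reported coefficients are on the original predictor
scales.

**Quadrature.** Default 15 nodes per dimension; at the study's variance
scale (ψ ≈ 0.003–0.026) the log-likelihood is stable to ~10⁻³ from 7
nodes up, which the test suite checks by node-doubling. The rule is
centered on the random-effect prior (the per-household posteriors at
these variance scales stay well inside the prior's node span, which the
Monte-Carlo agreement test confirms); fully adaptive per-household
recentering was not needed at these scales.

## Synthetic data

The generator emulates a household health survey of adults: households of
2–4 members (probabilities 0.7/0.2/0.1 — the source survey reports only
"2 or more"), predictors drawn at the survey's margins (age ~ truncated
normal 55.8 ± 18.4 on [16, 100], history prevalence 24.1%, householder
82.8%, closeness categories at the published frequencies, BMI 26.7 ± 5.3,
deprivation quintiles at the published shares). The co-resident flag X_co
is derived from the other members' history indicators, never sampled, so
its logical dependence on household composition is preserved; with
independent within-household history draws its prevalence comes out near
34% rather than the survey's 27.6% (real households correlate history
within household). The household closeness score Z_2 is the household
mean of members' individual closeness plus N(0, 0.1²) noise clipped to
[1, 5] — the survey does not describe its construction; the household
mean is an assumption, and it reproduces the published Z_2 dispersion
(≈ 0.63).

Default structural parameters are the published estimates (β, γ, ψ_Ind =
0.013, ψ_HH = 0.003) and default loadings the published unstandardized
pattern. Indicator residual variances follow the delta convention
Var(Y*_p) = 1 at the generating parameters, so thresholds are
standard-normal cut-points shifted by λ_p·E[η]; the default thresholds
reproduce the published item margins. E[η] and Var(β′X+γ′Z) are computed
by an internal fixed-seed Monte Carlo over the predictor distributions
(exact when all coefficients are zero), making default thresholds a
deterministic function of the configuration.

What the generator does **not** emulate: the survey's sampling design and
weights, non-response beyond MCAR missingness, within-household
correlation of predictors (beyond X_co and Z_2), multidimensional or
method-factor structure in the items, and the real predictor covariance
matrix. Consequently, passing tests demonstrate that the estimators
recover the parameters of this generating process — they do not certify
the substantive survey findings, and pipeline-level quantities that
depend on the predictor covariance structure (e.g. the share of variance
explained at each level) will differ from the published survey values
even at matching coefficients.

## Numerical choices and edge cases

- Polychoric ρ clipped at ±0.995; boundary → infinite asymptotic
  variance, replaced by the largest finite weight in the DWLS stage.
- Bivariate normal CDF by Owen's T with |z| capped at 8.5 (tail < 10⁻¹⁷)
  and exact-zero arguments nudged by 10⁻¹²; verified against scipy's
  reference implementation to ~10⁻¹⁵.
- DWLS start values from the first principal component of the polychoric
  matrix; the optimum is verified start-point-invariant in tests.
- A saturated specification reports F̂ = 0 and df = 0; RMSEA and TLI are
  then reported as not applicable rather than 0/0.
- Listwise deletion is applied once, globally, over all analysis
  variables before every stage, so all tables describe one analysis set.
  Households reduced to a single complete member by deletion remain in
  the analysis set (the two-or-adults rule is a design filter on the
  household, not on the complete cases).
- Degenerate inputs raise with the offending item/household named:
  one-category items, singleton households for the co-resident flag,
  non-increasing thresholds, negative variances.

## Problem sizes used in the checks

Test and acceptance runs use the survey's scale where the property needs
it (888 households, ≈ 2 140 individuals; 50 replicates for confidence-
interval coverage with 7-node quadrature) and smaller or larger sizes
where the property dictates (10⁶-draw Monte-Carlo integration oracles;
n ≈ 50 000 for marginal-frequency convergence; n ≈ 19 000 for loading
recovery). The coverage band [86%, 100%] is the exact binomial 95% band
for 50 replicates at nominal 95% coverage.

## Known limitations

- No mean/variance-corrected (robust) DWLS χ²; fit indices inherit this.
- Two-stage standard errors do not propagate stage-1 (threshold/loading)
  uncertainty into the structural stage.
- The ML backend is limited to two levels and a diagonal Θ; no survey
  weights; no longitudinal nesting; no cross-level interactions.
- Indicator ICCs are model-based on the latent-response scale
  (σ²_b/(σ²_b+1)); a linear decomposition of raw item scores would give
  different numbers.
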