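# Methods

## The model

`sf6dval` estimates a value set — a utility `u(x)` for every state `x` of
the SF-6D classification — from respondent-level adjusted standard-gamble
(SG) valuations, and lets one country's fitted posterior serve as the
informative prior for another country's analysis.

The measurement model for respondent `j`'s valuation of state `x_ij` is

    y_ij = 1 − α_j (1 − u(x_ij)) + ε_ij,     ε_ij ~ N(0, υ²)
    α_j  ~ LogNormal(t_j' γ_α, τ²)

Each respondent stretches or compresses their distance from full health by
a positive multiplicative factor `α_j`, modelled log-normally with
covariates `t_j` (intercept, optionally centered age and a sex indicator).
Adjusted SG values are bounded in [−1, 1] by the elicitation protocol; the
likelihood deliberately ignores the bounding (no censoring term) — the
bound is treated as a data-preparation fact, and the synthetic generator
clamps accordingly.

The utility function carries a multivariate-normal (GP) prior over the
lattice.  With `z(x) = levels(x) − 1` and the squared-exponential lattice
kernel

    c(x, x') = exp(−Σ_d b_d (x_d − x_d')²),

the two prior modes are

* standalone:  `E u(x) = 1 + γ₀ + β'z(x)`,          `cov = σ² c(x, x')`
* transfer:    `E u(x) = E u_base(x) + γ₀ + β'z(x)`, `cov = cov_base + σ² c(x, x')`

where `base` is another country's posterior (mean vector and covariance
matrix over a set of states), `γ₀ + β'z` is the systematic cross-country
correction, and `σ²` is the scale of the residual country difference.
Composing `posterior_as_prior` sequentially realises the n-country
generalisation (sums of means and covariances) with a single code path.

Two exact constraints resolve the multiplicative confounding between `α`
and the scale of `u`: the prior is conditioned exactly on
`u(full health) = 1` (Gaussian conditioning, not a penalty — every draw
and every prediction satisfies it), and the prior median of `α` is centred
at 1 by shrinking the intercept of `γ_α` (prior SD 0.05).

## Inference

Metropolis-within-Gibbs over `{u, α_j, γ_α, τ², υ², γ₀, β, σ², (b)}`:

* `u` — exact multivariate-normal full conditional (the likelihood is
  linear-Gaussian in `u` given the alphas).
* `α_j` — vectorised random-walk Metropolis on `log α_j` (all respondents
  proposed and accepted independently in one step; the per-respondent
  likelihood reduces to two sufficient statistics).
* `γ_α`, `τ²`, `υ²` — conjugate updates (normal regression on `log α`;
  inverse-gamma with prior IG(2, 0.05) for both variances).
* `(γ₀, β)` and `log σ²` (and optionally `log b_d`) — from **collapsed**
  conditionals with `u` integrated out: given the alphas, the records
  collapse to state-level weighted means that are Gaussian around the
  prior mean with covariance `V_c + diag(1/precision)`, so each update
  costs one small Cholesky.  `u` is redrawn from its full conditional
  immediately afterwards, which keeps the block update exact.  This
  matters: updating the covariance parameters against the latent `u`
  instead traps the chain — the field's own posterior noise masquerades as
  prior variance, `σ²` never shrinks, and the transfer prior can never
  learn that the base already explains the data.

Hyperpriors: `γ₀, β_d ~ N(0, 1)`; `log σ² ~ N(−6, 2²)` (median σ = 0.05,
95% range σ ∈ [0.007, 0.37] — genuinely weak on a [−1, 1] utility scale;
an earlier candidate `N(−3, 1)` proved informative at the wrong scale,
flooring σ² near 0.01 in small studies and wiping out the benefit of an
informative base); `b_d` fixed at 0.1 by default with an option to sample
`log b_d ~ N(log 0.1, 0.5²)`.  Chain defaults are 20,000 iterations,
5,000 burn-in, thinning 5; proposal scales are adapted during burn-in
toward 20–40% acceptance and frozen afterwards.  All experiments in the
test suite use shorter chains (typically 1,500 iterations, 500 burn-in,
thinning 2), which pilot checks showed are fully converged at these
problem sizes.

### Prediction and transfer

Predictions at design states are moments of the stored draws; full health
is the anchor (mean 1, SD 0); any other state is filled in per draw by
conditional-normal extension under that draw's covariance and
hyperparameters, with moments combined across draws by the laws of total
mean and variance.  `posterior_as_prior` packages mean and covariance
across (extended) draws at any chosen states, with negative-eigenvalue
clipping if draw noise leaves the matrix slightly indefinite.

When a transfer prior needs the base at states the base does not store,
the base is extended by universal kriging: a linear trend in centred
levels (anchored at full health) is fitted to the stored means and
extended exactly, and trend residuals are kriged under the lattice
kernel.  A constant-mean extension (plain kriging toward 1) was wrong in
an instructive way: remote states reverted toward full health, wrecking
off-design transfer predictions.  The residual variance scale of the
extension is the mean stored posterior variance — a heuristic, flagged in
the docstring, that matters only far from the stored states.

### Rebuilding a prior from a published table

`load_prior_from_table` reconstructs a country posterior from published
per-state means and SDs.  The published table carries no cross-state
covariances, so the covariance is approximated as `D R D` with
`D = diag(SD)` and `R` the kernel correlation at a chosen roughness.
This is an explicit, documented approximation: the original joint
posterior is not recoverable from printed marginals.

## The reference table and its printed statistics

`fixtures.load_table1` ships a 198-row transcription (197 valued states
plus full health) of the published Hong Kong study summary: observed mean
valuations and posterior mean/SD under the UK prior, the HK-only model
and the HK/UK transfer model.  The transcription is digest-checked and
validated by recomputing every published aggregate:

| statistic | HK | HK/UK | convention that reproduces the print |
|---|---|---|---|
| RMSE | 0.0517 (printed 0.051) | 0.045 | exclude full health |
| abs. mean bias | 0.0116 | 0.0175 | include the full-health row (198 rows) |
| SD of differences | 0.0503 | 0.0416 | exclude full health, population (n) denominator |
| LoA length | 0.197 | 0.163 | 3.92 × SD |

Findings a reader should know:

* The printed SDs verify only with the population denominator, so
  `bland_altman` defaults to `ddof=0` (pass `ddof=1` for the sample
  convention).
* The two printed mean-bias values verify only with the model attribution
  the table itself implies — 0.0116 for HK, 0.0175 for HK/UK.  The source
  narrative pairs them the other way; its own table does not support that
  pairing.
* HK RMSE recomputes to 0.0517 against a printed 0.051 — one unit in the
  last printed digit, attributable to the inputs being 4-dp roundings.
  The seven other statistics reproduce exactly at printed precision.
* The transfer-model posterior SDs are *smaller* than the HK-only SDs on
  only 23 of 197 non-anchored rows, contradicting the source narrative's
  claim that they are smaller; see "Known limitations" below, because the
  same structure appears in synthetic experiments.

## The synthetic-data generator

The surveys are not publicly deposited, so the generator emulates them:

* **Truth.**  `u(x) = 1 − h(Σ_d dec_d(x_d)) + perturbation`, floor-rescaled
  and anchored at 1.  The per-dimension decrement profiles total 0.68 at
  the pits (pits ≈ 0.32 before perturbation, the order of magnitude of
  published SF-6D value sets) and include near-flat adjacent levels, as
  published value sets do — strictly monotone, but with many adjacent
  pairs separated by well under 0.01.  `h(t) = t(1 + κt/t_max)/(1+κ)` is
  a monotone severity-curvature interaction (utility loss accelerates
  with overall severity): non-additive structure a linear prior mean
  cannot represent, which is precisely what a carried-over posterior can
  transfer.  The optional perturbation is a smooth correlated lattice
  field (sampled cheaply via the Kronecker structure of the separable
  kernel); unlike the curvature it can break monotonicity, so the
  two-country scenario keeps it small (scale 0.02).
* **Respondents and records.**  `α_j` log-normal (τ² = 0.04 → ~20%
  heterogeneity); Gaussian noise υ² = 0.02 (SG-scale noise); balanced
  random allocation of design states to respondents; completely-at-random
  missingness with an exact missing count; values clamped to [−1, 1].
* **Two countries.**  Country B's truth is country A's with per-dimension
  decrement reweights (defaults 0.85–1.3) plus a linear downward shift
  (default 0.05 at the pits, 0 at full health), sharing A's perturbation —
  so the systematic cross-country difference has exactly the
  offset-plus-linear form the transfer prior corrects, with a small
  nonlinear residual.  Default study designs reproduce the published
  surveys (A: 249 states × 611 respondents × 6 values, 148 missing; B:
  197 × 582 × 8, 60 missing); tests use scaled-down versions.  By default
  B re-values a subset of A's design states (`shared_design=True`): a
  target-country survey selects from the established design, and a
  carried posterior is informative exactly where the new study measures.

What the generator does **not** emulate: the ping-pong SG elicitation and
chaining arithmetic (values arrive already adjusted), informative
missingness, respondent exclusion from raw interviews, and any
non-multiplicative respondent effects.  Passing tests therefore show that
the inference machinery recovers the structure the model assumes, not
that the model is correct for real survey data.

## Evaluation battery

Observed − predicted differences throughout; aggregates exclude the
anchored full-health row by default.  The monotonicity audit samples
states without replacement, picks one neighbour (±1 level in one
dimension) uniformly at random per state, and counts a pair as
non-monotone when the dominance ordering conflicts with the predicted
ordering; ties count as violations by default (a value set should
strictly separate dominated states) and the audit is invariant to
strictly increasing transforms of the predictions.  Cost per QALY is
`cost / ΔQALY` rounded to the whole currency unit.

## Design choices on genuinely open points

* The "predicted valuation" compared against observed state means is the
  posterior mean of `u`, not of the population valuation
  `1 − E[α](1 − u)`; the source is silent on which it plots.
* γ appears in the source both as the α-model coefficient vector and as
  the scalar prior offset; here they are `gamma_alpha` and `gamma0`.
* Adjacency is ±1 level in exactly one dimension — the only definition
  consistent with "6–12 adjacent states"; neighbour choice in the audit
  is uniform.
* Whether `b_d` and `σ²` were fixed or estimated in the original analysis
  is unstated; `b_d` is fixed at 0.1 by default (sampling available),
  `σ²` is always sampled.

## Problem sizes used in the test suite

The synthetic experiments are scaled-down versions of the survey
designs: the two-country comparisons use 20 seeded scenarios with a
large prior country (60 design states, 300 respondents × 6 values) and a
small target study (30 states, 15 respondents × 6 values, ~87
observations), chains of 1,500 iterations (500 burn-in, thinning 2,
≈500 retained draws), monotonicity audits over 400 sampled states using
150 draws for the conditional extension, and parameter recovery over 20
replications at J = 100 respondents × 8 values on 30 design states.
Pilot runs at larger sizes and longer chains gave the same qualitative
behaviour.

## Known limitations

* **Posterior-SD comparisons.**  The transfer prior covariance is
  `cov_base + σ² c`, so the transfer posterior can have *smaller* SDs than
  the standalone posterior only when the standalone model's fitted σ²
  substantially exceeds the base uncertainty plus the transfer model's
  σ² — a narrow identifiability window.  In synthetic two-country
  experiments the transfer fit wins on accuracy (RMSE against truth)
  robustly, but its per-state posterior SDs are typically *not* smaller.
  The published table exhibits the same structure: HK/UK SDs are smaller
  than HK SDs on only 23/197 rows.  The package reports this honestly
  rather than engineering the comparison to pass.
* **Monotonicity-audit comparisons.**  The audit penalises local wiggle,
  not global error.  The transfer surface carries the base's true
  non-additive curvature as short-range bumps around the carried states,
  while the standalone surface reverts off-design to a globally smooth —
  hence monotone — linear trend.  In the synthetic scenarios the transfer
  fit is therefore usually *more* accurate but not more monotone than the
  standalone fit; a configuration in which the standalone surface is
  noisy lattice-wide (very long-range kernel plus noisy data) would be
  needed to reverse this, and deliberately degrading the baseline is not
  an honest comparison.
* The kernel-extension heuristic for bases at unstored states is only as
  good as the linear trend plus short-range kriging; far from the stored
  states it reverts to the trend.
* No censoring term for the ±1 bounds; studies with heavy mass at the
  bounds will bias υ² (visible in parameter-recovery experiments when
  design states sit near full health).
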