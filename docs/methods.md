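# Methods

This note records the statistical model behind `addint`, the numerical
choices that are not forced by the mathematics, and what the simulation
harness does and does not establish.

## Model and measures

Two binary exposures A and B define four joint categories
(A₀B₀, A₁B₀, A₀B₁, A₁B₁) — this order is fixed everywhere in the package.
The outcome follows Bernoulli logistic regression in indicator (dummy)
coding,

    logit p = β₀ + β₁·I(A₁B₀) + β₂·I(A₀B₁) + β₃·I(A₁B₁) + Xγ,

so the category odds ratios are ORⱼ = e^βⱼ. In a case-control design the
ORs stand in for relative risks (rare-disease approximation), giving

    RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1,   AP = RERI / OR₁₁,
    S = (OR₁₁ − 1) / (OR₁₀ + OR₀₁ − 2).

The product-term coding (η₀ + η₁A + η₂B + η₃AB) is converted on input via
β₃ = η₁+η₂+η₃; because the exposure-cell model is saturated the two
parameterizations carry identical information, and all downstream code sees
one coding.

**Domain of S.** S is meaningful only when every category carries excess
risk: OR₁₁ > 1 and OR₁₀ + OR₀₁ > 2. At points outside this domain the
package returns a tagged undefined value (with a diagnostic reason) rather
than raising, because resampled or posterior draws routinely wander outside
the domain even when the point estimate is inside; such draws are counted
and reported, never silently dropped. The same reasoning is applied to the
whole triple in the Bayesian summaries (below).

**Preventive factors.** When a factor is preventive the lowest-risk joint
category must become the reference before the measures are meaningful.
`recode_lowest_reference` subtracts the minimal category coefficient
(reference counting as 0) from all four and relabels the factors
(A\* = A⊕a_r, B\* = B⊕b_r); this is algebraically identical to refitting
the saturated model on physically recoded data (tested). Ties for the
minimum prefer the original reference, then the order A₁B₀, A₀B₁, A₁B₁ —
an arbitrary but fixed rule chosen for reproducibility.

## Fitting

Two equivalent routes:

* **Closed form for a 2×4 table** (no confounders): βⱼ is the log
  cross-product ratio against the A₀B₀ cell and the covariance is the
  analytic inverse information of the saturated binomial model
  (Var βⱼ = 1/caseⱼ + 1/controlⱼ + 1/case₀ + 1/control₀,
  Cov = 1/case₀ + 1/control₀). Any empty cell raises by default; an
  optional continuity-correction mode adds 0.5 to every cell and records
  that it did.
* **IRLS / Newton** for subject-level data with confounders: at most 100
  iterations, score-norm tolerance 1e−8, step-halving on likelihood
  decrease. Non-convergence (e.g. separation) is reported through a
  `converged=False` flag with the gradient norm, leaving the decision to
  the caller. The IRLS fit is checked against statsmodels and against the
  closed form (agreement to ≥ 8 significant digits on all-positive tables).

## Delta-method intervals

For Z ∈ {RERI, AP, ln S}, Var Z ≈ gᵀΣg with Σ the (β₁,β₂,β₃) block of the
full-model inverse information (confounders marginalised by matrix
inversion, the standard practice) and analytic gradients

    RERI: (−e^β₁, −e^β₂, e^β₃)
    AP:   (−e^{β₁−β₃}, −e^{β₂−β₃}, (e^β₁+e^β₂−1)e^{−β₃})
    ln S: (−e^β₁/D, −e^β₂/D, e^β₃/(e^β₃−1)),  D = e^β₁+e^β₂−2,

each verified against central finite differences to relative error < 1e−6.
Intervals are Ẑ ± z₁₋α/₂·SE, exponentiated for S. The normal quantile is
exact (1.959964… at 95%), not the rounded 1.96.

## Bootstrap

Resampling is with replacement separately within cases and within controls,
preserving the design's fixed margins. Without confounders this is
distributionally identical to multinomial resampling of the case and
control cell vectors, so all B refits use the vectorised closed form; with
confounders each resample is refit by IRLS (failures counted). Intervals:
percentile (Z\*_{α/2}, Z\*_{1−α/2}), basic (2Ẑ − Z\*_{1−α/2}, 2Ẑ − Z\*_{α/2}),
normal (Ẑ ± z·sd of draws). Quantiles are type-1 order statistics (index
⌈Bq⌉), a convention that must be fixed for bit-reproducibility. Default
B = 1000; the seed is a required argument with no hidden default.

**Empty reference cells.** When a resample has no unexposed cases all three
ORs diverge. The draw is recorded at its exact cases₀→0 limit: with
Kⱼ = casesⱼ·controls₀/controlsⱼ, RERI → ±∞ with the sign of K₁₁−K₁₀−K₀₁,
while AP → 1 − (K₁₀+K₀₁)/K₁₁ and S → K₁₁/(K₁₀+K₀₁) stay finite. Infinite
draws participate in the order statistics — this is what produces the
astronomically large percentile upper limits on sparse tables and is
reported honestly rather than truncated. Draws with no defined limit, and S
draws off-domain, are excluded from that measure's order statistics with
the count reported.

## Bayesian estimation

Priors are independent normals, by default N(0, 10²) on every coefficient —
proper but diffuse. The posterior is sampled by Gaussian random-walk
Metropolis with proposal covariance (2.38²/d)·Σ̂_MLE (the classical optimal
scaling; identity fallback with a warning if no MLE is available). Chain 1
starts at the MLE, later chains at the MLE plus overdispersed jitter
(2× proposal sd). Defaults: 20,000 iterations, 10,000 burn-in, 2 chains
pooled, no thinning. Acceptance rates (typically ≈ 0.3) and the
Gelman–Rubin PSRF per parameter are recorded; PSRF > 1.1 warns but does not
abort. When there are no confounders the likelihood is evaluated from the
eight cell counts (sufficient statistics) — algebraically identical to the
subject-level product, about two orders of magnitude faster, and tested
equal.

**Summaries and the draw policy.** Point estimates are posterior medians
(means reported in diagnostics); intervals are equal-tailed posterior
quantiles, with an HPD variant behind a flag. Because the measures
presuppose risk-factor coding, the default summaries are computed over the
posterior draws in which every category coefficient is non-negative (all
ORs ≥ 1); the excluded fraction is reported, and a summary built from fewer
than half the draws is flagged unreliable. This extends to the whole triple
the same domain logic used for S, and draws outside it are finite-sample
artifacts on sparse data (on the packaged example ≈ 10% of draws; in the
simulation scenarios effectively none, so coverage results are insensitive
to the policy). `include_nonrisk_draws=True` summarises the full posterior
instead, and `recode=True` re-references every draw at its own lowest-risk
category before evaluating the measures — the preventive-factor workflow,
in which each draw remains a coherent parameter state and all recoded draws
are risk-coded by construction. For data where all factors are clearly
risky the three policies coincide.

## Simulation harness

Twenty scenarios cross OR₀₁ ∈ {4, 2}, OR₁₀ ∈ {5, 2.5} and five OR₁₁ values
per pair, spanning AP = 0.60, 0.33, 0, −0.33, −1 (strong synergy to strong
antagonism). Control joint-exposure proportions are fixed at
(0.6, 0.1, 0.2, 0.1); designs are balanced (300/300), unbalanced (200/400)
or confounded.

* Without a confounder, controls are multinomial on q and cases multinomial
  on pⱼ ∝ qⱼ·ORⱼ, which makes the scenario ORs the exact population
  exposure odds ratios between cases and controls — the standard
  construction for case-control simulation with fixed margins.
* With a confounder, a source cohort is generated (exposure ~ q,
  X ~ N(0, 1) independent of exposure, disease from the logistic model with
  γ = 0.5 and intercept solved numerically for the design's case fraction)
  and the required case/control totals are sampled from it. Because X is
  independent of exposure it is a covariate rather than a true confounder —
  a limitation of the design, not of the estimators.

Per replicate the harness computes delta, percentile-bootstrap and/or
Bayesian intervals for all three measures and reports coverage of the true
value, left miscoverage (lower limit above truth), right miscoverage (upper
limit below truth, the three summing to 100% exactly), the median point
estimate, membership in the binomial target band 95 ± 1.96·√(0.95·0.05/R)·100
(93.6–96.4% at R = 1000), and the rank of |coverage − 95| across methods
(ties averaged). Replicate r of scenario s draws its RNG from
`SeedSequence(seed, spawn_key=(s, r))`, so any single replicate is
reproducible in isolation; bootstrap and MCMC seeds are spawned from the
same stream.

Directional note: with Wald (delta) intervals under strong synergy the
miscoverage is grossly lopsided — the interval falls entirely below the
true RERI in ≈ 6–7% of replicates and overshoots essentially never, the
expected behaviour for a symmetric interval on a right-skewed estimator
(and mirrored for the left-skewed AP). Bootstrap and Bayesian intervals
stay near the balanced 2.5%/2.5%.

## Problem sizes and tolerances

The default test suite and the acceptance script favour scaled problem
sizes chosen so Monte Carlo error stays well inside the tolerances being
checked: coverage runs use 300 replicates (binomial SE ≈ 1.3 points at 95%)
with a 5,000-retained + 5,000-burn-in single chain for the per-replicate
Bayesian interval — chain halving changes A3 coverage by far less than the
replicate noise — and 1,000 replicates for delta-only runs (SE ≈ 0.7).
Posterior-summary checks on the worked example pool draws over ten seeds so
that tail-quantile noise (sd ≈ 0.24 on the S upper limit per run) does not
dominate the comparison. The full 20-scenario × 1,000-replicate ×
three-method study runs overnight on one CPU via `addint simulate`.

## What the generator does not emulate

Synthetic samples have exactly the designed case/control totals, exposure
odds ratios constant across strata, and (in the confounded design) a single
Gaussian covariate acting multiplicatively on the odds. Real case-control
data add selection effects, misclassified exposures, correlated confounders
and non-rare outcomes (where the OR-for-RR substitution itself biases the
measures). Passing coverage here therefore validates the interval
machinery under the stated sampling model, not robustness to those
violations.

## Known limitations

* The percentile bootstrap's divergent upper limits on sparse tables are
  reported as ±∞ at the exact cell-limit; software that instead runs a
  finite number of IRLS iterations on separated resamples prints huge
  finite numbers (10⁶–10⁷) for the same draws — the substance (an unusable
  upper limit) is identical.
* Exact (conditional) logistic regression, Firth correction, BCa/studentised
  bootstraps, HMC/NUTS samplers and more-than-two-factor interactions are
  out of scope.
* S is reported as undefined (never extrapolated) when the point estimate
  itself falls outside S's domain; the delta interval for S then refuses to
  compute rather than guessing.
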