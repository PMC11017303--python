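# Methods

## Model

For a failure time `T` with covariates `X ∈ R^p`, observed as
`(Y, Δ) = (min(T, C), I(T ≤ C))` under conditionally independent right
censoring, the package fits the single-index hazard model

    λ(t | x) = λ(t) / r(xᵀβ),        t ∈ [0, τ],

where the link `r` is an unknown, positive, **nondecreasing** function
(equivalently `φ = −log r` is nonincreasing) and `λ` is an unspecified
baseline hazard with cumulative `Λ`. Two scale ambiguities are removed by
the identifiability constraints

    Λ(τ) = 1    and    ‖β‖ = 1.

With `r(z) = exp(−φ(z))` this is the familiar single-index relative-risk
model `λ(t|x) = λ(t) exp{φ(xᵀβ)}`; the Cox model is the special case
`φ(z) = z` up to the sign convention. The package always fits the
nondecreasing-`r` representation; the `direction="dec"` flag negates the
index internally and is purely a reporting convention, since the model
family is closed under joint negation of `β` and reflection of the link.

## Estimation

The semiparametric MLE maximizes the full likelihood

    L(β, r, Λ) = Π_i [λ(y_i)/r(x_iᵀβ)]^{δ_i} exp{−Λ(y_i)/r(x_iᵀβ)}

with `Λ` restricted to step functions jumping at event times and `r` to
nondecreasing step functions jumping at the distinct index values
`z_1* < … < z_L*` of *uncensored* observations. The inner loop, at fixed
`β`, alternates two closed-form updates to a fixed point:

- **(M1) link update.** Holding `Λ` fixed, the likelihood in the link
  values is that of `L` ordered exponential means: block `l` (interval
  `I_l = (z_{l−1}*, z_l*]`) has `m_l^d` uncensored subjects and block mean
  `η̄_l = (1/m_l^d) Σ_i Λ(y_i) I(z_i ∈ I_l)`, where *every* subject in the
  block contributes to the numerator. The constrained MLE is the weighted
  isotonic fit of `η̄` with weights `m_l^d`, computed by the stack-based
  pool-adjacent-violators algorithm (equal to the max–min of weighted
  running averages). Subjects beyond the last uncensored index
  (`I_{L+1}`, necessarily all censored) are assigned the last level
  `r_L` throughout — in the likelihood and in the risk sets — even though
  the unconstrained optimum for those terms would be `r = ∞`; this follows
  the update rule that defines the estimator.
- **(M2) hazard update.** Holding `r` fixed, the maximizer over `Λ` is the
  Breslow-type estimator
  `Λ*(t) = Σ_i δ_i I(y_i ≤ t) / Σ_j I(y_j ≥ y_i)/r(z_j)`, rescaled to
  `Λ = Λ*/Λ*(τ)`. Tied event times share one jump (Breslow convention:
  summed event count over the common risk-set denominator).

The alternation monotonically increases the full log-likelihood evaluated
after each (M1) step (the likelihood is invariant under the joint scaling
`(Λ/c, r/c)`, so (M2)'s normalization costs nothing); the test suite
asserts this ascent.

The profile log-likelihood at the fixed point,

    l_p(β) = Σ_i δ_i [log ΔΛ̂(y_i) − log r̂(z_i)] − Σ_i Λ̂(y_i)/r̂(z_i),

is maximized over the unit sphere in spherical coordinates
`β = S(θ)`, `θ ∈ [0, π]^{p−2} × [0, 2π]`, by Nelder–Mead (the surface is
piecewise constant in `β` — it depends only on the induced ordering and
grouping of the index values — so derivative-free search is required).
The first start is `S⁻¹(−β̂_P/‖β̂_P‖)`, the negative normalized Cox MPLE;
when covariates are elliptically symmetric that start is itself consistent
for the index direction, and in general it is a serviceable warm start.
After each converged run the incumbent `θ` is perturbed by independent
uniforms on `[−0.5, 0.5]` per coordinate and the search rerun; the new
solution replaces the incumbent only on a strict improvement. Twenty
restart rounds are the default.

## Numerical choices

- **Inner convergence.** Relative change of the link values plus absolute
  change of the cumulative hazard at its jump times below `tol = 1e−8`;
  at most 1000 cycles; start at `r ≡ 1` (the Cox-null start) with `Λ` the
  corresponding normalized Breslow estimate. Plain fixed-point iteration
  is the default; a pluggable accelerator hook (a SQUAREM-style
  extrapolation is provided) must reach the same fixed point and is
  exercised in the tests.
- **Tied indices.** Index values are grouped after rounding to 12
  significant digits; exact float equality is too brittle under reordered
  dot products. Tied event times use the Breslow convention. Times equal
  to machine precision are treated as exactly tied; no jittering.
- **Zero link values.** PAVA can return 0 when every `Λ(y)` in a leading
  block is 0; estimates report the true 0 and the value is floored at
  `1e−300` only inside logs and divisions. An event subject with
  `r̂(z) = 0` yields a `−inf` profile value, never a crash.
- **Simplex settings.** Termination is on the function value
  (`fatol = 1e−8`, `xatol = 1e−4`) with at most `500 p` evaluations per
  run. Proposals outside the angle box are wrapped: trailing angle modulo
  `2π`, the others reflected into `[0, π]`. Equal-likelihood restart
  candidates keep the first found, for determinism.
- **Caching.** `l_p(β)` depends on `β` only through the block assignment
  of all subjects, so the optimizer memoizes fixed points keyed on that
  assignment; the hot loop is compiled with numba.
- **Cox initializer.** In-repo Newton–Raphson with Breslow ties,
  step-halving, convergence at score sup-norm `< 1e−8`, and a
  monotone-likelihood guard (a vanishing score at `‖β‖_∞ > 10` is flagged
  as non-convergence). On failure the profile search starts at `θ = 0`
  with a warning.

## Uncertainty and prediction

Pointwise prediction uses `S(t|x) = exp{−Λ̂(t)/r̂(xᵀβ̂)}` for `t ≤ τ`
(no extrapolation beyond the identifiability horizon; note
`S(τ|x) = exp{−1/r̂(xᵀβ̂)}`). Coefficient uncertainty is by nonparametric
bootstrap: rows resampled with replacement, the model refitted per
replicate, componentwise percentile bounds at `(1±level)/2` from (default)
500 replicates. Replicates are sign-aligned with the point estimate before
taking percentiles, since the sign of `β̂` is a convention. The coverage
of percentile intervals for this estimator is not calibrated — the
asymptotic distribution of `β̂` is an open problem (the convergence rate
is only known to be at least `n^{1/3}`) — and the result object carries
that caveat. Analytic standard errors are out of scope for the same
reason.

## Synthetic-data generator

The simulation module reproduces the study design the estimator was
evaluated under. Given covariates `X`, failure times follow the hazard
`λ(t|X) = 2t / r(Xᵀβ*)` with `r(z) = exp{|z|^a sign(z)}` (so
`T = sqrt(r · E)`, `E ~ Exp(1)`, and the true normalized baseline is
`Λ₀(t) = t²/τ²`). The raw coefficients alternate `β*_{2m−1} = −1,
β*_{2m} = +1`; the identified target is `β₀ = β*/√p`. Scenarios:
(I) p=2 iid Exp(1); (II) p=2 iid N(0,1); (III) p=5 with X1,X2 ~ Exp(1),
X3 ~ Bernoulli(1/2), X4,X5 ~ N(0,1); (IV) p=5 iid N(0,1); exponents
`a ∈ {1/5, 1/3, 1}` (`a = 1` is a correctly specified Cox model with
coefficient `−β*`). Censoring is `C = min(C*, τ)`, `C* ~ Exp(λ_C)`.

The pair `(λ_C, τ)` is under-determined by the single target censoring
rate, and only the rate (25% or 50%) is part of the study conditions, so
the generator pins `τ` at the 0.90 quantile of the marginal failure-time
distribution and solves for `λ_C` by bisection against a fixed-seed Monte
Carlo sample of 10⁶ draws (rate tolerance ±0.002; `τ` falls back to the
0.95 / 0.99 quantile if the administrative floor alone exceeds the
target). Calibration is deterministic given its own seed, which is
independent of the study seed.

What the generator does **not** emulate: covariate measurement error,
dependent or covariate-driven censoring, ties in observed times (its
times are continuous), and real-data covariate scales or correlation.
Passing the simulation benchmarks therefore shows correct behaviour under
the generator's clean sampling assumptions, not robustness to violations
of conditionally independent censoring or to heavily discretized data.

The Monte Carlo study helper derives per-replicate seeds from the study
seed via `SeedSequence(entropy=seed, spawn_key=(replicate,))`, so cells
reproduce exactly and can be parallelized; failed replicates are excluded
and counted. Summaries report empirical bias and SD of `β̂ − β₀`
(both ×1000) with Monte Carlo standard errors.

## Problem sizes used by the shipped benchmarks

The bias benchmarks for the misspecified Cox comparator use the study's
own cells (1000 replicates at n=800 or n=200). The variability benchmark
for the shape-restricted estimator uses 200 replicates at n=200 — the SD
estimate then carries a Monte Carlo standard error of about 5% of its
value, which the comparison tolerance accounts for. Consistency checks
for the fitted `β̂` and `Λ̂` run at n=2000.

## Known limitations

- `r̂` is a step function; no smoothing or monotone-spline variant is
  provided, and unimodal links are not supported (only the monotone
  direction flag).
- No left truncation, interval censoring, time-varying covariates or
  stratification.
- The outer search is local-with-restarts on a piecewise-constant
  surface; with very small samples distinct orderings can tie and the
  reported maximizer is then one representative of a set.
- Bootstrap intervals are percentile-only (no BCa) and uncalibrated.
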