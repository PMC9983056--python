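# Methods

## Model

`jointbin` fits a shared random-effects joint model for two bounded
count outcomes and a survival time. Conditional on a subject's random
effects b, the paired scores at each visit are independent draws from
the bivariate extended binomial — the product of two Altham-type
extended binomial kernels gⱼ(y) = C(mⱼ,y) pⱼ^y (1−pⱼ)^{mⱼ−y} θⱼ^{y(mⱼ−y)}
times an association factor ϕ^{y₁y₂}, renormalized over the finite
(m₁+1)×(m₂+1) support. This distribution carries the residual
association between the two tests in a single parameter ϕ instead of
forcing the random effects to absorb it. Success probabilities are
logistic in time with per-response intercepts and slopes, optional
time-constant covariates, and random effects restricted to one of four
two-dimensional structures (shared intercept+slope; intercepts only;
slopes only; effects on the second response only). The hazard is
Weibull (λτt^{τ−1}) or Gompertz (λe^{ξt}) with λ = e^β, multiplied by
exp(Δ) where the link Δ = δ₀ + δ₁t is built from α-weighted
random-intercept terms (δ₀) and/or random-slope terms (δ₁), plus
survival covariates. Absorbing Δ gives individual-specific parameters
λ* = exp(β + δ₀) and, for the Gompertz, ξ* = ξ + δ₁, so the model stays
in-family at the subject level.

Outcomes are conditionally independent given b ~ N(0, Σ) with
Σ parameterized by (σ₁, σ₂, ρ). The marginal likelihood integrates the
longitudinal × survival contribution over b and divides by the
marginal probability of surviving to the entry age (delayed entry).

## Estimation

- **Quadrature.** Both integrals use the same product Gauss–Hermite
  rule mapped through the Cholesky factor of Σ (equivalent to
  integrating the conditional-normal factorization dimension by
  dimension). Sharing the grid makes the truncation correction cancel
  exactly when entry is at time 0. Default 7 nodes per dimension.
  Measured accuracy at the default design: the 7-node rule is within
  ~5×10⁻² of the converged value per subject (worst case), 15→31
  refinement changes the total by < 10⁻⁴ per subject, and a 40-node
  rule agrees with an independent adaptive-integration oracle to
  ~10⁻⁷. Seven nodes is a deliberate speed/accuracy compromise whose
  adequacy is demonstrated by the parameter-recovery study rather than
  by per-subject error.
- **Transforms.** θ, ϕ, τ/ξ, σ on the log scale; ρ via tanh/atanh;
  everything else identity. The inverse maps are clamped
  (exp at ±500, |ρ| ≤ 1−10⁻¹²) so optimizer excursions cannot leave the
  domain.
- **Optimizer.** L-BFGS-B on the free scale with finite-difference
  gradients, relative-ftol 10⁻⁷, projected-gradient tolerance 10⁻⁶, and
  a wide free-space box (identity coordinates ±30, log coordinates
  [−7, 4], atanh(ρ) ±6). The box exists because the marginal likelihood
  has genuine degenerate ridges — σ₁ → 0 with |α|, |β| → ∞ at roughly
  constant ασ₁ — along which small cohorts sometimes place their
  maximum; a solution on the box boundary is classified non-converged.
  Starting values: per-response binomial-logistic fits ignoring random
  effects for η; θ = ϕ = 1; σ = 0.5; ρ = 0; β from the crude
  exponential rate log(deaths/exposure); ξ = 0.1 or τ = 1; α = γ = 0.
  Single-start by default with an optional seeded multi-start.
- **Standard errors.** Central-difference Hessian of the negative
  log-likelihood in free space (step 10⁻⁴(1+|x|)), inverted and mapped
  to the natural scale by the delta method. A non-positive-definite
  Hessian yields undefined SEs with a warning; the point estimates are
  retained.
- **Linear predictors** are clipped at ±35 before the logistic, keeping
  p strictly inside (0,1) without affecting any realistic fit.
- Two equivalent likelihood routes exist: a literal per-subject
  composition of the submodules and a vectorized evaluator used by the
  optimizer; tests pin them together to ~10⁻⁹ across all model
  families.

## Synthetic cohorts and the simulation study

`simulate_cohort` emulates a fixed-design longitudinal ageing study:
every subject enters at time 0, visits are scheduled every 3 years up
to a 24-year horizon (at most nine visits), counts are drawn by exact
inverse-CDF from the fully enumerated bivariate support (a
Metropolis–Hastings sampler is retained only as a cross-check oracle),
and the death time inverts the subject's own survivor function in
closed form. Visits are emitted strictly before the death time, so
every subject keeps at least the baseline visit. The default generating
values — η₀ = (1.0, 0.8), η₁ = (−0.2, −0.2), θ = (1, 1), ϕ = 0.8,
Gompertz (β = −1.5, ξ = 0.1), link α = −0.4 through Y₁'s random
intercept, σ = (0.4, 0.6), ρ = 0.3, scores on 0..10 — define the study
conditions used by the tests and the acceptance script. Under them
essentially every subject dies within the horizon (median survival
≈ 5 years, ~2–3 visits per subject), so the survival part is
information-rich and the longitudinal part deliberately sparse.

What the generator does *not* emulate about real cohort data: delayed
entry at varying baseline ages (simulated entry is always 0; the
truncation machinery is exercised separately), integer-rounded ages,
missed interviews/intermittent missingness, practice effects, and
covariate-driven heterogeneity beyond what is configured. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated design, not robustness to those real-data
features.

`run_study` is the ADEMP harness: replicate r simulates with an
independent child stream seeded from (base_seed, r), refits from the
default starts, excludes non-converged replicates (counted, and the
report is flagged above 20% exclusions; if fewer than two replicates
converge the report falls back to summarizing all of them, flagged),
and reports truth, mean, bias, |%bias|, empirical SE,
mc_se_bias = emp_se/√R and mc_se_empse = emp_se/√(2(R−1)) per
parameter. Identical configuration gives bit-identical reports. The
test suite and acceptance script run the study at 30 replicates of
N = 100 — the scale chosen to keep a full run on one core in minutes —
while the harness accepts any N/replicate count for larger studies.

## Prediction

MAP random effects maximize longitudinal likelihood + survival density
(with the subject's recorded event status) + N(0, Σ) prior over the
free effects, by the same quasi-Newton machinery started at the prior
mode; a subject with a single observation uses t_last = t₁. Fitted
score distributions and expectations come from the exact pmf table at
the implied (p₁, p₂, θ, ϕ). Predicted survival curves evaluate the
subject-specific survivor function; the Kaplan–Meier comparison uses
lifelines with entry times honored, so subjects join risk sets only
from their entry age (configurable off). For ξ* values within 10⁻⁸ of
zero (possible under slope links), survivor evaluation switches to the
exponential-limit branch to avoid 0/0.

## Design choices on genuinely open points

- The truncation denominator shares the numerator's quadrature grid
  (makes entry-at-0 cancel exactly).
- Individual ξ* may be negative even though the population ξ is
  constrained positive; a negative draw can make a simulated subject
  immortal, returned as t = ∞ and censored at the horizon.
- The Weibull uses the scale-parameter absorption λ* = exp(β + δ₀);
  slope links are rejected for the Weibull family since they would make
  the shape time-dependent.
- Covariates are subject-level (time-constant) vectors with one
  coefficient per covariate per response (γ_L) and per hazard (γ_S).
- The MAP objective uses the recorded death indicator for decedents
  rather than forcing censored status; predictions are produced for the
  whole cohort, decedents included.
- Ages are stored raw in data files and rescaled on load (default
  offset 49), so "model time" ≈ years since age 49; the offset is a
  data-schema setting, not a constant.

## Known limitations

- Exactly two longitudinal responses and a 2-D random-effect space; no
  multivariate (>2) extension.
- No adaptive (per-subject recentered) quadrature; subjects whose
  posteriors sit far from the prior are the ones that need more nodes.
- Finite-difference gradients make fitting O(k) likelihood evaluations
  per iteration; N = 1000 fits take on the order of a minute each.
- α is weakly identified in small cohorts; its sampling distribution is
  heavy-tailed and occasional replicates settle on the degenerate ridge
  described above (excluded via the boundary rule).
- Confidence-interval coverage, landmark/dynamic prediction and
  B-spline age effects are out of scope.
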