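# Methods

## Model

For subject i = 1..n with n_i binary observations y_ij, the mixed-effects
logistic model is

    logit P(y_ij = 1 | b_i) = x_ij' β + z_ij' b_i,     b_i ~ N_q(0, Q),

with fixed effects β (length p) and subject random effects b_i (the default
random design is an intercept, z_ij = 1, q = 1).  Collinearity among the
columns of X makes X'WX nearly singular and inflates Var(β̂); the ridge
variant adds an L2 penalty on the fixed effects.

The random-effects integral is handled with the penalized-quasi-likelihood
(Breslow–Clayton) approximation: estimation maximizes the joint criterion

    ℓ_λ(β, b) = Σ_ij [ y_ij η_ij − log(1 + e^{η_ij}) ] − λ β'Mβ − ½ b'(I_n ⊗ Q^{-1}) b,

where M is a 0/1 diagonal selecting the penalized coefficients (a
user-data intercept is excluded by default, configurable via
`penalize_intercept`).  λ = 0 gives the unpenalized baseline ("MELM" in the
package's vocabulary); λ > 0 the ridge fit ("RMELM").

Gradient (score) and curvature are available in closed form.  The penalized
Fisher information has arrowhead structure — a p×p fixed-effect block
X'ΨX + 2λM, n cross blocks X_i'Ψ_i Z_i, and n subject blocks
Z_i'Ψ_i Z_i + Q^{-1}, with Ψ = diag(π(1−π)) — and all solves go through the
q×q subject blocks plus the p×p Schur complement, never the dense
(p + nq)² matrix.  Note the b-gradient is −Q^{-1}b_i, the derivative of the
−½ b'Q^{-1}b term; a `printed_b_gradient` flag doubles it to reproduce a
published variant of the formula that is inconsistent with that penalty
(verified against numerical differentiation).

## Fitting

Each outer iteration performs, in order:

1. **Ridge parameter** (auto mode, see below).
2. **δ = (β, b) update**: one gradient-ascent step with the Rayleigh step
   size ϑ = s's / s'F_λs, then one Fisher-scoring step δ ← δ + F_λ^{-1}s,
   recomputing score and information between the two.  Both half-steps are
   guarded by step-halving (≤10 halvings) whenever the penalized criterion
   would decrease; the bare updates can overshoot at poor starts, and the
   guard makes the criterion trace monotone for fixed (λ, Q).
3. **EM covariance update**: Q ← (1/n) Σ_i (v_ii + b̂_i b̂_i'), where v_ii is
   the i-th diagonal block of F_λ^{-1} (posterior covariance of b_i),
   computed via the Schur complement.  The result is symmetrized and its
   eigenvalues floored at 1e-8.

Initialization: β from a pooled logistic IRLS fit, b = 0, Q = I.

**Convergence** is declared when max|Δδ| < tol·(max|δ|+1) and
‖ΔQ‖_F < tol·(‖Q‖_F+1), both at tol = 1e-6, within 200 outer iterations.
The tolerances are scale-relative with an absolute guard because two
regimes defeat purely elementwise relative criteria: (i) when Q̂ heads to
the boundary, the b̂_i decay geometrically to zero with a per-iteration
*relative* change that never shrinks; (ii) the EM sequence for Q contracts
slowly (ratio → 1) near small fixed points.  For (ii) the package also
applies a guarded Aitken Δ² extrapolation to the Q sequence every 8
iterations: the vector ratio r = ⟨ΔQ_s, ΔQ_{s-1}⟩/‖ΔQ_{s-1}‖² must indicate
a stable contraction (0 < r < 0.9999) and the extrapolated matrix must be
symmetric positive definite, otherwise the plain EM iterate stands.  This
cuts worst-case iteration counts from thousands to well under a hundred
without changing the fixed point.

Non-convergence is reported on the result (`converged=False` with the
criterion trace), not raised.  |η| > 30 triggers a quasi-separation warning.

### Known behavior of the EM variance update

For binary data with only two observations per subject, the EM update
based on the Laplace-approximate posterior underestimates Q — increasingly
so as the true variance grows.  This is a known property of this estimator
family (maximum-likelihood and working-model REML fitters such as
`lme4::glmer` or `MASS::glmmPQL` are less affected), and it is retained
deliberately as part of the implemented algorithm.  Consequently the λ=0
fixed effects are attenuated toward the pooled-model values at high ICC;
see "Simulation study" below for what that implies about the Monte Carlo
summaries.

## Ridge parameter

With Ŵ = diag(π̂(1−π̂)) at the current fit (η including the random-effect
contributions), eigendecompose X'ŴX = γ'Λγ over the penalized columns,
rotate α̂ = γβ̂, and form m_k = sqrt(σ̂²/α̂_k²).  Two orientations of the
geometric-mean rule circulate in the applied ridge literature:

* `rule="kibria"` (default): λ = (∏ m_k)^{1/p} = σ̂ / gm|α̂_k|.  This is the
  Hoerl–Kennard/Kibria convention (k ∝ σ̂²/α̂²): rotated coefficients that
  are small relative to the dispersion — exactly what collinearity's small
  eigenvalues produce — attract hard shrinkage.  In the simulation design
  it yields λ ≈ 2–6.
* `rule="inverse"`: λ = (∏ 1/m_k)^{1/p} = gm|α̂_k| / σ̂, the mirror image.
  For coefficient vectors below 1 in norm it yields λ < 1 and is nearly
  inert; it cannot deliver the variance reductions ridge tuning exists
  for, and is provided for comparison.

λ depends only on |α̂_k|, so eigenvector ordering and sign conventions do
not affect it (asserted by test).  σ̂² defaults to 1 (fixed Bernoulli
dispersion, the common choice for logistic ridge); a Pearson χ²/(N−p)
estimate is available (`sigma2_mode="pearson"`).

**Update schedule.**  By default λ is estimated once, from the pooled
initial fit (`lambda_update="init"`).  Re-estimating every outer iteration
(`lambda_update="every"`) is available but is *not* the default for the
kibria orientation: shrinking β̂ lowers gm|α̂|, which raises λ, which shrinks
β̂ further — a positive feedback that in experiments drove λ above 10⁵ and
collapsed β̂ to zero in a quarter of small-sample replicates.  The one-shot
schedule is stable and reproduces the intended bias/variance trade-off.

## Inference

The fixed-effect covariance defaults to the sandwich form: the β block of
F_λ^{-1} F_0 F_λ^{-1}, with F_0 the information at the same state with
λ = 0 (random-effect precision retained) — the mixed-model analogue of
(X'WX+2λI)^{-1}(X'WX)(X'WX+2λI)^{-1}.  A `naive` mode returns the β block
of F_λ^{-1}; the two coincide at λ = 0, and the naive form is smaller for
λ > 0.  Because the ridge estimator is biased, t = β̂/SE is a *non-exact*
t-test; the reference distribution uses df = N − p by default, with a
normal option.  The global test is a likelihood-ratio test on the
unpenalized joint criterion at the respective estimates, χ² with
df = p_full − p_null.

Collinearity diagnostics follow the Belsley convention: columns scaled to
unit length (no centering), condition indices sqrt(μ_1/μ_j) of the scaled
cross-product's eigenvalues, condition number = largest index (reported
infinite, with a warning, for exact collinearity), plus the plain
correlation matrix.

## Simulation study

The generator emulates a two-occasion design: n ∈ {30, 50, 100} subjects,
2 observations each; three unit-variance normal predictors of which x₁ and
x₂ share a common factor, x_k = sqrt(1−ρ)a_k + sqrt(ρ)c, so corr(x₁,x₂)=ρ
∈ {0.7, 0.8, 0.9, 0.95} while x₃ is independent; true β = (0.2, 0.4, −0.3);
random intercepts with σ_b² = ICC·(π²/3)/(1−ICC) for ICC ∈ {0.2, 0.5, 0.8}
(the latent-logistic-scale convention).  A variant recipe that reuses a_k
in both terms (available as `printed_form=True`) leaves the pair
uncorrelated whatever ρ and exists only for comparison.  Replicate streams
derive from (master seed, cell index, replicate index) via `SeedSequence`
spawn keys, so any worker count reproduces the same numbers.

Per replicate both models are fitted (λ=0 and λ auto); summaries are
per-coefficient MSE, relative bias 100·(mean β̂_k − β_k)/β_k, empirical
power of the two-sided non-exact t-test at α = 0.05, and the mean Q̂.
Non-converged replicates are excluded and counted (warning above 5%).
Default reps = 1000; the shipped acceptance runs use 500 for the single
cell and 200 per grid cell, sizes at which one cell takes seconds and the
36-cell grid minutes on one core.

What the generator does *not* emulate: covariate measurement error,
unbalanced cluster sizes, missing visits, or non-normal random effects —
passing tests show correctness of the estimator machinery under the stated
design, not robustness to those features of real data.

Observed behavior worth knowing before comparing models on real data:

* the λ=0 estimator's MSE for the collinear pair inflates steeply with ρ
  (≈5× from ρ=0.7 to 0.95 at n=30, ICC=0.2) while the ridge estimator's
  MSE stays flat and an order of magnitude lower, at the price of 20–45%
  negative bias;
* because of the EM variance underestimation (above), λ=0 estimates are
  themselves attenuated at ICC ≥ 0.5, so grid-wide median |relative bias|
  is ≈30% for the λ=0 fit and ≈48% for the ridge fit under these
  conditions;
* empirical power of the non-exact t-test with sandwich SEs is near the
  nominal level for the tiny β₁ = 0.2 at n = 30 — the test is roughly
  calibrated rather than anticonservative.

## Numerical choices

* probabilities clamped to [1e-10, 1−1e-10] in weight/log evaluations
  (logged);
* |α̂_k| floored at 1e-8 in the shrinkage rule (the λ→0 limit, logged);
* EM covariance eigenvalues floored at 1e-8;
* criterion evaluated in softplus form (`logaddexp`), stable for |η| large;
* CSV round trips use shortest-repr floats on write and round-trip parsing
  on read, so written datasets reload bit-exactly.

## Limitations

One grouping factor only; canonical logit link only; no quadrature-based
marginal likelihood, REML, or bootstrap intervals.  The non-exact t-test's
reference distribution is an approximation whose df choice (N − p) is a
convention, not a derived null law.  Q̂ from the EM update should not be
interpreted as an unbiased variance-component estimate for short panels.
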