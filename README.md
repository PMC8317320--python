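# rmelm — ridge mixed-effects logistic regression

Collinear predictors are endemic in public-health data: exposure scores
(e.g. the financial/sexual/physical/psychological facets of intimate
partner violence) correlate at 0.5–0.8, the determinant of X'WX collapses,
and a mixed-effects logistic model (MELM) fitted to clustered binary
outcomes returns inflated standard errors and "nothing significant".
`rmelm` implements a ridge-penalized mixed-effects logistic model (RMELM)
for exactly this situation, together with the unpenalized baseline, a
closed-form rule for the ridge parameter, inference for the penalized
coefficients, collinearity diagnostics, and a Monte Carlo harness that
quantifies what the penalty buys.

The model for observation j of subject i is

    logit P(y_ij = 1 | b_i) = x_ij'β + z_ij'b_i,   b_i ~ N_q(0, Q),

and estimation maximizes the penalized Breslow–Clayton criterion

    ℓ_λ = Σ_ij [y_ij η_ij − log(1 + e^{η_ij})] − λ β'β − ½ b'(I_n ⊗ Q^{-1}) b

by alternating a hybrid gradient-ascent/Fisher-scoring update for (β, b)
— solved through the arrowhead block structure of the penalized Fisher
information — with an EM update for Q.  The ridge parameter comes from a
closed-form geometric-mean rule on eigen-rotated coefficients,
λ = (∏_k m_k)^{1/p} with m_k = sqrt(σ̂²/α̂_k²).  Standard errors use a
sandwich form and coefficients are tested with a non-exact t-test.  See
`docs/methods.md` for the full account.

## Worked example

`python examples/monte_carlo_cell.py` simulates 100 two-visit studies of
30 subjects with two predictors collinear at ρ = 0.9 (ICC 0.2, true
β = (0.2, 0.4, −0.3)) and fits both models to each:

```
plain (MELM)
  MSE        0.575     0.461     0.095
  bias%       30.2     -10.8       5.2
  power       0.04      0.02      0.11
ridge (RMELM)
  MSE        0.043     0.060     0.050
  bias%       10.7     -42.1     -34.4
  power       0.21      0.28      0.12

MSE(plain) / MSE(ridge): [13.4  7.7  1.9]
```

β₁ and β₂ load on the collinear pair: the unpenalized estimator's error
explodes there (MSE 0.58 for a coefficient of 0.2) while the ridge
estimator accepts some shrinkage bias and cuts the MSE by an order of
magnitude.  β₃'s predictor is independent, so it gains far less.
`examples/fit_collinear_longitudinal.py` runs the single-dataset workflow
(diagnostics → both fits → SE comparison → global LRT) and
`examples/shrinkage_rule.py` dissects the λ rule.

The same workflows are scriptable from the shell:

```sh
rmelm fit --data study.csv --lambda auto --out results/
rmelm simulate --n 30 --icc 0.2 --rho 0.9 --reps 200 --seed 1 --out results/
rmelm diagnose --data study.csv --out results/
```

Input CSVs are long-format with `subject`, binary `y`, fixed-effect
columns, and optional `z_*` random-effect columns (default: random
intercept).

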