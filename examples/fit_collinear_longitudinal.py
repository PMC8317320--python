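"""Fit ridge and unpenalized mixed-effects logistic models to collinear data.

Builds a synthetic two-visit study of a binary outcome (e.g. depression
before/after an intervention): four strongly inter-correlated exposure
scores, a treatment-group indicator and a time indicator, with a subject
random intercept.  The ridge fit should report visibly smaller standard
errors on the collinear exposures than the unpenalized fit.
"""

import numpy as np

from rmelm import (
    FitConfig,
    LongitudinalDesign,
    collinearity_diagnostics,
    fit,
    lrt_global,
)

rng = np.random.default_rng(7)
n, visits = 150, 2
N = n * visits

# four correlated exposure scores via a shared latent factor
common = np.repeat(rng.standard_normal(n), visits)
expo = 0.75 * common[:, None] + 0.55 * rng.standard_normal((N, 4))
group = np.repeat(rng.integers(0, 2, n), visits).astype(float)
time = np.tile(np.arange(visits, dtype=float), n)
X = np.column_stack([group, time, expo])
names = ("group", "time", "financial", "sexual", "physical", "psychological")

b = rng.normal(0, 1.0, n)
eta = X @ np.array([0.4, -0.6, 0.5, 0.35, 0.25, 0.15]) + np.repeat(b, visits)
y = (rng.random(N) < 1 / (1 + np.exp(-eta))).astype(float)
design = LongitudinalDesign.from_arrays(
    np.repeat(np.arange(n), visits), y, X, x_names=names
)

diag = collinearity_diagnostics(X[:, 2:], names=names[2:])
print(f"condition number of the exposure block: {diag.condition_number:.1f}")
print("(values above ~10 signal collinearity strong enough to inflate SEs)\n")

plain = fit(design, FitConfig(lambda_mode="zero"))
ridge = fit(design, FitConfig(lambda_mode="auto"))

print("unpenalized fit (lam = 0):")
print(plain.to_frame().round(3), "\n")
print(f"ridge fit (lam = {ridge.lam_used:.2f}, estimated from the data):")
print(ridge.to_frame().round(3), "\n")

shrink = 100 * (1 - ridge.se_beta / plain.se_beta)
for name, s in zip(names, shrink):
    print(f"  SE reduction for {name:13s}: {s:5.1f}%")
print("\nridge trades a little bias on the collinear exposures for much")
print("smaller standard errors, so their effects become estimable.")

stat, df, p = lrt_global(
    plain,
    fit(
        LongitudinalDesign.from_arrays(
            np.repeat(np.arange(n), visits), y, X[:, :1], x_names=names[:1]
        ),
        FitConfig(lambda_mode="zero"),
    ),
)
print(f"\nglobal LRT of the 5 extra fixed effects: chi2({df}) = {stat:.1f}, "
      f"p = {p:.2g}")
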