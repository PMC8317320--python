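"""One cell of the Monte Carlo comparison: ridge vs unpenalized fits.

Simulates clustered binary data (30 subjects, 2 observations each, two
predictors collinear at rho = 0.9, ICC = 0.2) and summarizes mean squared
error, relative bias and empirical power of both estimators over 100
replicates.  Expect the ridge estimator to trade bias for a many-fold MSE
reduction on the collinear pair.
"""

import numpy as np

from rmelm import SimulationCell, run_cell

cell = SimulationCell(n=30, icc=0.2, rho=0.9, reps=100, seed=42)
melm, rmelm = run_cell(cell)

print(f"cell: n={cell.n} subjects, ICC={cell.icc}, rho={cell.rho}, "
      f"true beta = {cell.beta_true}\n")
hdr = f"{'':8s}" + "".join(f"{c:>10s}" for c in ("beta1", "beta2", "beta3"))
for label, m in (("plain", melm), ("ridge", rmelm)):
    print(f"{label} ({m.model})")
    print(f"{'  MSE':8s}" + "".join(f"{v:10.3f}" for v in m.mse))
    print(f"{'  bias%':8s}" + "".join(f"{v:10.1f}" for v in m.rel_bias_pct))
    print(f"{'  power':8s}" + "".join(f"{v:10.2f}" for v in m.power))
    print(f"  mean estimated random-intercept variance: {m.mean_Q:.2f}\n")

gain = melm.mse / rmelm.mse
print("MSE(plain) / MSE(ridge):", np.round(gain, 1))
print("beta1 and beta2 load on the collinear pair, so that is where the")
print("ridge penalty buys the largest error reduction; beta3's predictor")
print("is independent and gains less.")
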