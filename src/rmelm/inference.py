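"""Inference for penalized mixed-effects logistic fits.

Standard errors come from a sandwich form: with F_lam the penalized and
F_0 the unpenalized (lam = 0, random-effect precision retained) Fisher
information at the converged state, the fixed-effect covariance is the
beta block of

    F_lam^{-1}  F_0  F_lam^{-1},

the mixed-model analogue of the logistic-ridge formula
(X'WX + 2 lam I)^{-1} (X'WX) (X'WX + 2 lam I)^{-1}.  Because the ridge
estimator is biased, t = beta_hat / SE is a *non-exact* t-test: the
reference distribution is an approximation, not an exact null law.  A
"naive" mode returns the beta block of F_lam^{-1} instead (the two
coincide at lam = 0).

Also here: the global likelihood-ratio test and Belsley-style collinearity
diagnostics (condition indices of the unit-length-scaled cross-product).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimation import FitResult
from .model import FisherBlocks


@dataclass(frozen=True)
class CoefficientTest:
    name: str
    estimate: float
    se: float
    t_value: float
    df: float
    p_value: float
    odds_ratio: float
    significant: bool


@dataclass(frozen=True)
class CollinearityDiagnostics:
    condition_number: float
    condition_indices: np.ndarray
    correlation: np.ndarray
    eigenvalues: np.ndarray
    names: tuple

    def to_dict(self) -> dict:
        return {
            "condition_number": float(self.condition_number),
            "condition_indices": [float(v) for v in self.condition_indices],
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "correlation": self.correlation.tolist(),
            "names": list(self.names),
        }


def sandwich_cov_beta(
    fisher_penalized: FisherBlocks,
    fisher_unpenalized: FisherBlocks,
    mode: str = "sandwich",
) -> np.ndarray:
    """Fixed-effect covariance from the converged Fisher blocks.

    ``sandwich``: beta block of F_lam^{-1} F_0 F_lam^{-1}, computed from the
    first p columns of F_lam^{-1} obtained by arrowhead solves.
    ``naive``: beta block of F_lam^{-1}, i.e. the inverse Schur complement.
    """
    p = fisher_penalized.p
    if mode == "naive":
        return np.linalg.inv(fisher_penalized.schur_complement())
    if mode != "sandwich":
        raise ValueError(f"unknown variance mode {mode!r}")
    E = np.zeros((fisher_penalized.dim, p))
    E[:p, :p] = np.eye(p)
    G = fisher_penalized.solve(E)                 # first p columns of F_lam^{-1}
    cov = G.T @ fisher_unpenalized.matvec(G)
    return 0.5 * (cov + cov.T)


def reference_df(N: int, p: int, df_mode: str = "t") -> float:
    """Degrees of freedom for the non-exact t reference: N - p, or inf."""
    if df_mode == "t":
        return float(max(N - p, 1))
    if df_mode == "normal":
        return np.inf
    raise ValueError(f"unknown df_mode {df_mode!r}")


def wald_tests(beta: np.ndarray, se: np.ndarray, df: float):
    """t = beta/SE and two-sided p from a t (or normal) reference."""
    se = np.asarray(se, dtype=float)
    if (se == 0).any():
        raise ZeroDivisionError("zero standard error in Wald test")
    t = np.asarray(beta, dtype=float) / se
    if np.isinf(df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def coefficient_tests(fit: FitResult, alpha: float = 0.05) -> list[CoefficientTest]:
    """Per-coefficient non-exact t-tests with rejection flags at ``alpha``."""
    out = []
    for name, b, s, t, pv, o in zip(
        fit.x_names, fit.beta_hat, fit.se_beta, fit.t_stats,
        fit.p_values, fit.odds_ratios,
    ):
        out.append(
            CoefficientTest(
                name=name, estimate=float(b), se=float(s), t_value=float(t),
                df=float(fit.df), p_value=float(pv), odds_ratio=float(o),
                significant=bool(pv < alpha),
            )
        )
    return out


def lrt_global(fit_full: FitResult, fit_null: FitResult):
    """Global likelihood-ratio test of the extra fixed effects in ``fit_full``.

    Uses the *unpenalized* joint log-likelihoods at the respective estimates;
    the null fit must be the nested model on the same data.
    Returns (statistic, df, p_value).
    """
    if fit_full.n_obs != fit_null.n_obs or fit_full.n_subjects != fit_null.n_subjects:
        raise ValueError("LRT requires both fits on the same data")
    df = len(fit_full.x_names) - len(fit_null.x_names)
    if df < 0:
        raise ValueError("null model has more fixed effects than the full model")
    statistic = 2.0 * (fit_full.loglik_unpenalized - fit_null.loglik_unpenalized)
    if df == 0:
        p = 1.0
    else:
        p = float(stats.chi2.sf(statistic, df))
    return float(statistic), int(df), p


def collinearity_diagnostics(X: np.ndarray, names=None) -> CollinearityDiagnostics:
    """Belsley-style condition diagnostics of the predictor matrix.

    Columns are scaled to unit length (no centering); with eigenvalues
    mu_1 >= ... >= mu_p of the scaled cross-product, the condition indices
    are sqrt(mu_1 / mu_j) and the condition number is the largest of them.
    The plain correlation matrix of the columns is returned alongside.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("collinearity diagnostics require at least 2 columns")
    if names is None:
        names = tuple(f"x{j + 1}" for j in range(X.shape[1]))
    var = X.var(axis=0)
    if (var == 0).any():
        j = int(np.flatnonzero(var == 0)[0])
        raise ValueError(f"column {names[j]!r} has zero variance")
    norms = np.linalg.norm(X, axis=0)
    Xs = X / norms
    mu = np.linalg.eigvalsh(Xs.T @ Xs)[::-1]          # descending
    mu = np.clip(mu, 0.0, None)
    tiny = mu[0] * np.finfo(float).eps * X.shape[1]
    if (mu <= tiny).any():
        warnings.warn(
            "exactly collinear columns: smallest eigenvalue is 0, condition "
            "number reported as infinite",
            RuntimeWarning,
            stacklevel=2,
        )
    indices = np.where(mu > tiny, np.sqrt(mu[0] / np.maximum(mu, tiny)), np.inf)
    return CollinearityDiagnostics(
        condition_number=float(indices.max()),
        condition_indices=indices,
        correlation=np.corrcoef(X, rowvar=False),
        eigenvalues=mu,
        names=tuple(names),
    )
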