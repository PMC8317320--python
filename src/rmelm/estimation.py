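"""Fitting the (ridge) mixed-effects logistic model.

The outer loop alternates updates until joint convergence:

1. ridge parameter: in ``auto`` mode, estimated by the closed-form
   geometric-mean rule — once from the pooled initial fit by default
   (``lambda_update="init"``), or afresh each outer iteration (``"every"``);
2. delta = (beta, b): one gradient-ascent step with the Rayleigh step size
   theta = s's / s'Fs, followed by one Fisher-scoring step solved through
   the arrowhead block structure (q x q subject solves + p x p Schur
   complement), each guarded by step-halving on the penalized criterion;
3. Q: the EM variance-component update
   Q <- (1/n) sum_i (v_ii + b_i b_i') with v_ii the posterior covariance
   blocks extracted from the penalized Fisher information.

``lambda_mode="zero"`` gives the unpenalized mixed-effects logistic fit
(the MELM baseline); ``"auto"`` the ridge fit (RMELM); a float fixes lam.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import LongitudinalDesign
from .model import (
    FisherBlocks,
    ModelState,
    fisher_information,
    linear_predictor,
    penalized_loglik,
    score,
    unpenalized_loglik,
)
from .shrinkage import estimate_lambda

logger = logging.getLogger(__name__)

#: eigenvalue floor applied to the EM covariance update
Q_EIG_FLOOR = 1e-8


class NonPositiveCurvatureError(np.linalg.LinAlgError):
    """s'Fs <= 0: the penalized Fisher matrix is not positive definite."""


@dataclass(frozen=True)
class FitConfig:
    """Optimizer controls; the defaults fit most problems.

    lambda_mode : "auto" | "zero" | float
        "auto" estimates the ridge parameter with the closed-form rule
        (per ``lambda_rule``/``lambda_update``), "zero" fixes lam = 0
        (the unpenalized baseline), a float fixes lam.
    """

    lambda_mode: object = "auto"
    lambda_rule: str = "kibria"       # or "inverse"; see shrinkage module
    lambda_update: str = "init"       # "init": once from the pooled start;
                                      # "every": re-estimated each outer iter
    max_outer_iter: int = 200
    tol_delta: float = 1e-6
    tol_Q: float = 1e-6
    step_halving_max: int = 10
    update_Q: bool = True             # False freezes Q at Q_init (no EM step)
    Q_init: float = 1.0               # initial Q = Q_init * I_q
    sigma2_mode: str = "unit"
    variance_mode: str = "sandwich"   # or "naive"
    df_mode: str = "t"                # or "normal"
    alpha: float = 0.05
    penalize_intercept: bool = False
    seed: int = 0                     # reserved for optional jittered restarts

    def __post_init__(self):
        if self.max_outer_iter < 1:
            raise ValueError("max_outer_iter must be >= 1")
        if self.tol_delta <= 0 or self.tol_Q <= 0:
            raise ValueError("tolerances must be > 0")
        if isinstance(self.lambda_mode, str):
            if self.lambda_mode not in ("auto", "zero"):
                raise ValueError(f"unknown lambda_mode {self.lambda_mode!r}")
        elif float(self.lambda_mode) < 0:
            raise ValueError("fixed lambda must be >= 0")
        if self.lambda_update not in ("init", "every"):
            raise ValueError(f"unknown lambda_update {self.lambda_update!r}")


@dataclass
class FitResult:
    """Converged estimates plus inference, mirroring a coefficient table."""

    beta_hat: np.ndarray
    b_hat: np.ndarray
    Q_hat: np.ndarray
    lam_used: float
    cov_beta: np.ndarray
    se_beta: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    odds_ratios: np.ndarray
    loglik_penalized: float
    loglik_unpenalized: float
    converged: bool
    n_iter: int
    trace: np.ndarray
    x_names: tuple
    n_subjects: int
    n_obs: int
    df: float
    variance_mode: str
    config: FitConfig

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table: estimate, SE, odds ratio, t, p."""
        return pd.DataFrame(
            {
                "estimate": self.beta_hat,
                "se": self.se_beta,
                "odds_ratio": self.odds_ratios,
                "t_value": self.t_stats,
                "p_value": self.p_values,
            },
            index=list(self.x_names),
        )

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                name: {
                    "estimate": float(b), "se": float(s), "odds_ratio": float(o),
                    "t_value": float(t), "p_value": float(pv),
                }
                for name, b, s, o, t, pv in zip(
                    self.x_names, self.beta_hat, self.se_beta,
                    self.odds_ratios, self.t_stats, self.p_values,
                )
            },
            "lambda": float(self.lam_used),
            "Q": self.Q_hat.tolist(),
            "loglik_penalized": self.loglik_penalized,
            "loglik_unpenalized": self.loglik_unpenalized,
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "n_subjects": int(self.n_subjects),
            "n_obs": int(self.n_obs),
            "df": float(self.df),
            "variance_mode": self.variance_mode,
            "trace": [float(v) for v in self.trace],
        }

    def to_json(self, path=None, **kwargs) -> str:
        s = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def step_size(score_vec: np.ndarray, fisher: FisherBlocks) -> float:
    """Rayleigh step size theta = s's / s'Fs for the gradient-ascent step."""
    num = float(score_vec @ score_vec)
    if num == 0.0:
        raise ValueError("step_size requires a nonzero score vector")
    den = fisher.quad_form(score_vec)
    if den <= 0.0:
        raise NonPositiveCurvatureError(
            f"s'Fs = {den:g} <= 0: penalized Fisher information is not "
            "positive definite"
        )
    return num / den


def _pooled_logistic_irls(
    X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> np.ndarray:
    """Plain IRLS for pooled logistic regression (initialization only)."""
    p = X.shape[1]
    beta = np.zeros(p)
    jitter = 1e-8 * np.eye(p)
    for _ in range(max_iter):
        eta = X @ beta
        pi = expit(eta)
        w = np.clip(pi * (1 - pi), 1e-10, None)
        g = X.T @ (y - pi)
        H = (X * w[:, None]).T @ X + jitter
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _halved_ascent(design, state, step, ll0, max_halvings):
    """Apply ``step`` to delta, halving while the penalized criterion drops."""
    for _ in range(max_halvings + 1):
        cand = state.with_delta(state.delta + step)
        ll = penalized_loglik(design, cand)
        if np.isfinite(ll) and ll >= ll0 - 1e-12:
            return cand, ll
        step = 0.5 * step
    return cand, ll


def hybrid_update(
    design: LongitudinalDesign,
    state: ModelState,
    fisher: FisherBlocks | None = None,
    step_halving_max: int = 10,
) -> ModelState:
    """One gradient-ascent step then one Fisher-scoring step on delta.

    The score and Fisher blocks are recomputed between the two half-steps;
    the scoring solve runs through the arrowhead structure.  Both half-steps
    are guarded by step-halving on the penalized criterion.  At a stationary
    point the state is returned unchanged.
    """
    pi = expit(linear_predictor(design, state))
    s1 = score(design, state, pi=pi)
    if float(s1 @ s1) == 0.0:
        return state
    if fisher is None:
        fisher = fisher_information(design, state, pi=pi)
    ll0 = penalized_loglik(design, state)
    theta = step_size(s1, fisher)
    state, ll0 = _halved_ascent(design, state, theta * s1, ll0, step_halving_max)

    pi = expit(linear_predictor(design, state))
    s2 = score(design, state, pi=pi)
    F2 = fisher_information(design, state, pi=pi)
    step = F2.solve(s2)
    state, _ = _halved_ascent(design, state, step, ll0, step_halving_max)
    return state


def em_update_Q(state: ModelState, fisher: FisherBlocks) -> np.ndarray:
    """EM update Q <- (1/n) sum_i (v_ii + b_i b_i'), symmetrized and floored.

    ``fisher`` must be evaluated at ``state``; v_ii are its posterior
    subject blocks (diagonal blocks of the inverse information).
    """
    v = fisher.posterior_blocks()                       # (n, q, q)
    B = state.b[:, :, None] * state.b[:, None, :]
    Q = (v + B).mean(axis=0)
    Q = 0.5 * (Q + Q.T)
    eigs, vecs = np.linalg.eigh(Q)
    if (eigs < Q_EIG_FLOOR).any():
        logger.info("EM covariance eigenvalue floored at %g", Q_EIG_FLOOR)
        eigs = np.maximum(eigs, Q_EIG_FLOOR)
        Q = (vecs * eigs) @ vecs.T
        Q = 0.5 * (Q + Q.T)
    return Q


def _aitken_Q(q0: np.ndarray, q1: np.ndarray, q2: np.ndarray) -> np.ndarray | None:
    """Aitken delta-squared extrapolation of the EM covariance sequence.

    The EM update for Q contracts only slowly near its fixed point (the
    per-iteration ratio approaches 1 when the estimate is small relative to
    the posterior spread), so the geometric tail is jumped with a vector
    Aitken step.  Returns None when the local ratio is not a stable
    contraction, in which case the plain EM iterate stands.
    """
    d1, d2 = q1 - q0, q2 - q1
    denom = float(d1 @ d1)
    if denom <= 0.0:
        return None
    r = float(d2 @ d1) / denom
    if not (0.0 < r < 0.9999):
        return None
    q_acc = q2 + d2 * (r / (1.0 - r))
    if not np.all(np.isfinite(q_acc)):
        return None
    return q_acc


def fit(
    design: LongitudinalDesign,
    config: FitConfig = FitConfig(),
    penalize_mask: np.ndarray | None = None,
) -> FitResult:
    """Fit the model; ``lambda_mode`` selects MELM (zero) or RMELM (auto).

    Initialization: beta from a pooled logistic fit, b = 0, Q = I_q.
    Non-convergence is reported via ``FitResult.converged``, not raised.
    """
    from . import inference  # deferred: inference imports this module's types

    if design.n < 2:
        raise ValueError("at least 2 subjects are required")
    if penalize_mask is None:
        penalize_mask = design.default_penalize_mask()
        if config.penalize_intercept:
            penalize_mask = np.ones(design.p, dtype=bool)

    beta0 = _pooled_logistic_irls(design.X, design.y)
    state = ModelState(
        beta=beta0,
        b=np.zeros((design.n, design.q)),
        Q=config.Q_init * np.eye(design.q),
        lam=0.0,
        penalize_mask=penalize_mask,
    )
    auto = config.lambda_mode == "auto"
    Xp = design.X[:, penalize_mask]

    def _auto_lambda(st: ModelState) -> float:
        pi = expit(linear_predictor(design, st))
        return estimate_lambda(
            Xp, st.beta[penalize_mask], pi,
            sigma2_mode=config.sigma2_mode, y=design.y, rule=config.lambda_rule,
        )

    if not auto:
        lam = 0.0 if config.lambda_mode == "zero" else float(config.lambda_mode)
        state = replace(state, lam=lam)
    elif config.lambda_update == "init":
        state = replace(state, lam=_auto_lambda(state))

    trace = []
    q_hist = []
    converged = False
    it = 0
    for it in range(1, config.max_outer_iter + 1):
        if auto and config.lambda_update == "every":
            state = replace(state, lam=_auto_lambda(state))
        delta_old = state.delta
        Q_old = state.Q

        state = hybrid_update(design, state, step_halving_max=config.step_halving_max)
        if config.update_Q:
            F = fisher_information(design, state)
            Q_new = em_update_Q(state, F)

            # jump the slow geometric tail of the EM covariance sequence
            q_hist.append(Q_new.ravel().copy())
            if len(q_hist) > 3:
                q_hist.pop(0)
            if it % 8 == 0 and len(q_hist) == 3:
                q_acc = _aitken_Q(*q_hist)
                if q_acc is not None:
                    cand = q_acc.reshape(Q_new.shape)
                    cand = 0.5 * (cand + cand.T)
                    eigs = np.linalg.eigvalsh(cand)
                    if eigs.min() > 0:
                        Q_new = cand
                        q_hist.clear()
            state = replace(state, Q=Q_new)
        else:
            Q_new = state.Q
        trace.append(penalized_loglik(design, state))

        # change measured against the overall parameter scale (+1 absolute
        # guard), so entries decaying geometrically to zero cannot stall it
        d_ok = np.max(np.abs(state.delta - delta_old)) < config.tol_delta * (
            np.max(np.abs(delta_old)) + 1.0
        )
        q_ok = np.linalg.norm(Q_new - Q_old) < config.tol_Q * (
            np.linalg.norm(Q_old) + 1.0
        )
        if d_ok and q_ok:
            converged = True
            break

    eta = linear_predictor(design, state)
    if np.max(np.abs(eta)) > 30:
        warnings.warn(
            "very large linear predictors: possible (quasi-)separation",
            RuntimeWarning,
            stacklevel=2,
        )

    F_pen = fisher_information(design, state)
    F_unpen = fisher_information(design, replace(state, lam=0.0))
    cov_beta = inference.sandwich_cov_beta(F_pen, F_unpen, mode=config.variance_mode)
    se = np.sqrt(np.diag(cov_beta))
    df = inference.reference_df(design.N, design.p, config.df_mode)
    t_stats, p_values = inference.wald_tests(state.beta, se, df)

    return FitResult(
        beta_hat=state.beta,
        b_hat=state.b,
        Q_hat=state.Q,
        lam_used=float(state.lam),
        cov_beta=cov_beta,
        se_beta=se,
        t_stats=t_stats,
        p_values=p_values,
        odds_ratios=np.exp(state.beta),
        loglik_penalized=penalized_loglik(design, state),
        loglik_unpenalized=unpenalized_loglik(design, state),
        converged=converged,
        n_iter=it,
        trace=np.asarray(trace),
        x_names=design.x_names,
        n_subjects=design.n,
        n_obs=design.N,
        df=df,
        variance_mode=config.variance_mode,
        config=config,
    )
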