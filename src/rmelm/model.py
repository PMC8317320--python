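"""Penalized quasi-likelihood primitives for the ridge mixed-effects logistic model.

The model for observation j of subject i is

    logit P(y_ij = 1 | b_i) = x_ij' beta + z_ij' b_i,      b_i ~ N_q(0, Q).

Integrating the random effects with the Breslow–Clayton (penalized
quasi-likelihood) approximation and adding an L2 (ridge) penalty on the
fixed effects gives the working criterion maximized by the fitter:

    l_lam(beta, b) = sum_ij [ y_ij eta_ij - log(1 + exp(eta_ij)) ]
                     - lam * beta' M beta  -  (1/2) b' (I_n x Q^{-1}) b,

where M is a 0/1 diagonal selecting the penalized fixed effects (an
intercept is conventionally left unpenalized).  This module evaluates the
criterion, its gradient (score), and the blocked penalized Fisher
information; the blocks exploit the arrowhead sparsity (subject blocks are
mutually independent given beta).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from .design import LongitudinalDesign

logger = logging.getLogger(__name__)

#: probabilities are clamped to [PROB_EPS, 1 - PROB_EPS] in weight/log evaluations
PROB_EPS = 1e-10


class SingularQError(np.linalg.LinAlgError):
    pass


@dataclass(frozen=True)
class ModelState:
    """One point in parameter space: delta = (beta, b) plus Q and lam.

    ``b`` is stored subject-major with shape (n, q); the packed vector
    ``delta`` is ``[beta, b.ravel()]``.
    """

    beta: np.ndarray          # (p,)
    b: np.ndarray             # (n, q)
    Q: np.ndarray             # (q, q) SPD
    lam: float = 0.0
    penalize_mask: np.ndarray | None = None   # (p,) bool; None = penalize all

    def __post_init__(self):
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float).ravel())
        b = np.asarray(self.b, dtype=float)
        if b.ndim == 1:
            b = b[:, None]
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "Q", np.atleast_2d(np.asarray(self.Q, dtype=float)))
        if self.lam < 0:
            raise ValueError(f"ridge parameter lam must be >= 0, got {self.lam}")
        if self.penalize_mask is not None:
            m = np.asarray(self.penalize_mask, dtype=bool).ravel()
            if m.shape[0] != self.beta.shape[0]:
                raise ValueError("penalize_mask length does not match beta")
            object.__setattr__(self, "penalize_mask", m)

    @property
    def p(self) -> int:
        return self.beta.shape[0]

    @property
    def n(self) -> int:
        return self.b.shape[0]

    @property
    def q(self) -> int:
        return self.b.shape[1]

    @property
    def mask(self) -> np.ndarray:
        if self.penalize_mask is None:
            return np.ones(self.p, dtype=bool)
        return self.penalize_mask

    @property
    def delta(self) -> np.ndarray:
        return np.concatenate([self.beta, self.b.ravel()])

    def with_delta(self, delta: np.ndarray) -> "ModelState":
        p = self.p
        new = replace(
            self, beta=delta[:p].copy(), b=delta[p:].reshape(self.b.shape).copy()
        )
        # Q is unchanged: carry over its cached factorization
        for attr in ("_Qcho", "_Qinv"):
            if hasattr(self, attr):
                object.__setattr__(new, attr, getattr(self, attr))
        return new

    def Q_cho(self):
        try:
            return self._Qcho
        except AttributeError:
            pass
        try:
            c = cho_factor(self.Q, lower=True)
        except np.linalg.LinAlgError as err:
            raise SingularQError(
                f"random-effects covariance Q is not positive definite: Q={self.Q!r}"
            ) from err
        object.__setattr__(self, "_Qcho", c)
        return c

    def Q_inv(self) -> np.ndarray:
        try:
            return self._Qinv
        except AttributeError:
            pass
        qinv = cho_solve(self.Q_cho(), np.eye(self.q))
        object.__setattr__(self, "_Qinv", qinv)
        return qinv


def _check_shapes(design: LongitudinalDesign, state: ModelState) -> None:
    if state.p != design.p or state.n != design.n or state.q != design.q:
        raise ValueError(
            f"shape mismatch between design (p={design.p}, n={design.n}, "
            f"q={design.q}) and state (p={state.p}, n={state.n}, q={state.q})"
        )


def linear_predictor(design: LongitudinalDesign, state: ModelState) -> np.ndarray:
    """eta_ij = x_ij' beta + z_ij' b_i, stacked over all rows."""
    _check_shapes(design, state)
    return design.X @ state.beta + np.einsum(
        "nq,nq->n", design.Z, state.b[design.group_index]
    )


def fitted_probabilities(design: LongitudinalDesign, state: ModelState) -> np.ndarray:
    return expit(linear_predictor(design, state))


def penalized_loglik(
    design: LongitudinalDesign, state: ModelState, eta: np.ndarray | None = None
) -> float:
    """Ridge-penalized Breslow–Clayton joint log-likelihood (the criterion above)."""
    if eta is None:
        eta = linear_predictor(design, state)
    data = float(design.y @ eta - np.logaddexp(0.0, eta).sum())
    bm = state.beta[state.mask]
    pen_beta = state.lam * float(bm @ bm)
    pen_b = 0.5 * float(np.sum(state.b * (state.b @ state.Q_inv())))
    return data - pen_beta - pen_b


def unpenalized_loglik(design: LongitudinalDesign, state: ModelState) -> float:
    """The same joint criterion with the ridge term removed (lam = 0)."""
    return penalized_loglik(design, replace(state, lam=0.0))


def score(
    design: LongitudinalDesign,
    state: ModelState,
    pi: np.ndarray | None = None,
    printed_b_gradient: bool = False,
) -> np.ndarray:
    """Gradient of the penalized criterion w.r.t. delta = (beta, b).

    beta block:  sum_ij (y_ij - pi_ij) x_ij - 2 lam beta  (penalized entries)
    b_i block:   sum_j (y_ij - pi_ij) z_ij - Q^{-1} b_i

    ``printed_b_gradient=True`` doubles the Q^{-1} b_i term, reproducing a
    published variant of the formula that is inconsistent with the
    -1/2 b'Q^{-1}b penalty; it exists for comparison only.
    """
    _check_shapes(design, state)
    if pi is None:
        pi = fitted_probabilities(design, state)
    r = design.y - pi
    g_beta = design.X.T @ r
    g_beta[state.mask] -= 2.0 * state.lam * state.beta[state.mask]
    factor = 2.0 if printed_b_gradient else 1.0
    g_b = design.group_sum(design.Z * r[:, None]) - factor * state.b @ state.Q_inv()
    return np.concatenate([g_beta, g_b.ravel()])


def psi_weights(pi: np.ndarray) -> np.ndarray:
    """Diagonal of Psi = D nu^{-1} D' for the canonical logit link: pi (1 - pi).

    Probabilities at 0 or 1 are clamped to [PROB_EPS, 1 - PROB_EPS].
    """
    pi = np.asarray(pi, dtype=float)
    if (pi <= 0).any() or (pi >= 1).any():
        logger.warning(
            "fitted probabilities at 0/1 clamped to [%g, %g]", PROB_EPS, 1 - PROB_EPS
        )
        pi = np.clip(pi, PROB_EPS, 1 - PROB_EPS)
    return pi * (1.0 - pi)


@dataclass
class FisherBlocks:
    """Penalized Fisher information F_lam in arrowhead block form.

    F_bb : (p, p)      fixed-effect block  X' Psi X + 2 lam diag(mask)
    F_bi : (n, p, q)   cross blocks        X_i' Psi_i Z_i
    F_ii : (n, q, q)   subject blocks      Z_i' Psi_i Z_i + Q^{-1}

    Subject-subject off-diagonal blocks are identically zero, so solves and
    quadratic forms run through the q x q blocks and the p x p Schur
    complement instead of the dense (p + nq) matrix.
    """

    F_bb: np.ndarray
    F_bi: np.ndarray
    F_ii: np.ndarray

    _cinv: np.ndarray | None = None
    _schur: np.ndarray | None = None

    @property
    def p(self) -> int:
        return self.F_bb.shape[0]

    @property
    def n(self) -> int:
        return self.F_bi.shape[0]

    @property
    def q(self) -> int:
        return self.F_ii.shape[1]

    @property
    def dim(self) -> int:
        return self.p + self.n * self.q

    def assemble(self) -> np.ndarray:
        """Dense (p + nq) x (p + nq) matrix; for small problems and tests."""
        p, n, q = self.p, self.n, self.q
        F = np.zeros((self.dim, self.dim))
        F[:p, :p] = self.F_bb
        for i in range(n):
            sl = slice(p + i * q, p + (i + 1) * q)
            F[:p, sl] = self.F_bi[i]
            F[sl, :p] = self.F_bi[i].T
            F[sl, sl] = self.F_ii[i]
        return F

    def _factorize(self) -> None:
        if self._schur is not None:
            return
        if self.q == 1:
            d = self.F_ii[:, 0, 0]
            if (d <= 0).any():
                raise np.linalg.LinAlgError(
                    "singular subject block in Fisher information; consider a "
                    "larger ridge parameter or check for separation"
                )
            self._cinv = (1.0 / d)[:, None, None]
        else:
            try:
                self._cinv = np.linalg.inv(self.F_ii)
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    "singular subject block in Fisher information; consider a "
                    "larger ridge parameter or check for separation"
                ) from err
        # S = F_bb - sum_i F_bi C_i^{-1} F_bi'
        T = self.F_bi @ self._cinv                       # (n, p, q)
        self._schur = self.F_bb - np.tensordot(T, self.F_bi, axes=([0, 2], [0, 2]))

    def schur_complement(self) -> np.ndarray:
        """F_bb - sum_i F_bi F_ii^{-1} F_ib (the marginal beta information)."""
        self._factorize()
        return self._schur

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """F @ v through the blocks; v may be (dim,) or (dim, k)."""
        one_d = v.ndim == 1
        V = v[:, None] if one_d else v
        p, n, q = self.p, self.n, self.q
        Vb, Vi = V[:p], V[p:].reshape(n, q, -1)
        top = self.F_bb @ Vb + np.tensordot(self.F_bi, Vi, axes=([0, 2], [0, 1]))
        bot = np.swapaxes(self.F_bi, 1, 2) @ Vb + self.F_ii @ Vi
        out = np.concatenate([top, bot.reshape(n * q, -1)])
        return out[:, 0] if one_d else out

    def quad_form(self, s: np.ndarray) -> float:
        return float(s @ self.matvec(s))

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Solve F x = rhs via the arrowhead structure (never forms F densely)."""
        self._factorize()
        one_d = rhs.ndim == 1
        R = rhs[:, None] if one_d else rhs
        p, n, q = self.p, self.n, self.q
        Rb, Ri = R[:p], R[p:].reshape(n, q, -1)
        CiRi = self._cinv @ Ri                                  # (n, q, k)
        rb = Rb - np.tensordot(self.F_bi, CiRi, axes=([0, 2], [0, 1]))
        try:
            xb = np.linalg.solve(self._schur, rb)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular penalized Fisher information; consider a larger "
                "ridge parameter or check for separation"
            ) from err
        xi = CiRi - self._cinv @ (np.swapaxes(self.F_bi, 1, 2) @ xb)
        out = np.concatenate([xb, xi.reshape(n * q, -1)])
        return out[:, 0] if one_d else out

    def posterior_blocks(self) -> np.ndarray:
        """Diagonal subject blocks v_ii of F^{-1}, shape (n, q, q).

        v_ii = C_i^{-1} + C_i^{-1} F_ib S^{-1} F_bi C_i^{-1} with
        C_i = F_ii and S the Schur complement; these are the posterior
        covariances of b_i used by the EM variance update.
        """
        self._factorize()
        Sinv = np.linalg.inv(self._schur)
        # T_i = C_i^{-1} F_ib  (n, q, p)
        T = self._cinv @ np.swapaxes(self.F_bi, 1, 2)
        return self._cinv + (T @ Sinv) @ np.swapaxes(T, 1, 2)


def fisher_information(
    design: LongitudinalDesign, state: ModelState, pi: np.ndarray | None = None
) -> FisherBlocks:
    """Penalized Fisher information at ``state`` in arrowhead block form.

    With lam = 0 and Q^{-1} -> 0 the assembled matrix reduces to A' Psi A,
    A = [X, Z-blocks].
    """
    _check_shapes(design, state)
    if pi is None:
        pi = fitted_probabilities(design, state)
    w = psi_weights(pi)
    Xw = design.X * w[:, None]
    F_bb = Xw.T @ design.X
    F_bb[np.diag_indices_from(F_bb)] += np.where(state.mask, 2.0 * state.lam, 0.0)
    # segmented products: X_i' Psi_i Z_i and Z_i' Psi_i Z_i
    F_bi = design.group_sum(Xw[:, :, None] * design.Z[:, None, :])
    Zw = design.Z * w[:, None]
    F_ii = design.group_sum(Zw[:, :, None] * design.Z[:, None, :]) + state.Q_inv()
    return FisherBlocks(F_bb=F_bb, F_bi=F_bi, F_ii=F_ii)
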