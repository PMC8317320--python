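"""Long-format clustered binary data.

A :class:`LongitudinalDesign` holds the stacked per-observation design of a
mixed-effects logistic model: one row per observation, grouped by subject.
``X`` carries the fixed-effect covariates, ``Z`` the random-effect covariates
(an intercept-only random design, ``Z`` a column of ones, is the common case).
Rows are reordered so that each subject's rows are contiguous; subjects need
not be contiguous, or even sorted, in the source file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DesignError(ValueError):
    """Raised when the long-format data violate a structural requirement."""


def _as_2d(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise DesignError(f"{name} must be a 2-d array, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class LongitudinalDesign:
    """Stacked design matrices and responses for ``n`` subjects.

    Attributes
    ----------
    subject_ids : ndarray, shape (N,)
        Original subject labels, one per row, grouped contiguously.
    y : ndarray, shape (N,)
        Binary responses (0/1, stored as float).
    X : ndarray, shape (N, p)
        Fixed-effect covariates.
    Z : ndarray, shape (N, q)
        Random-effect covariates.
    group_index : ndarray, shape (N,)
        Row -> subject position in ``0..n-1``.
    group_starts : ndarray, shape (n,)
        First row of each subject block (for segmented reductions).
    """

    subject_ids: np.ndarray
    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    group_index: np.ndarray
    group_starts: np.ndarray
    x_names: tuple = ()
    z_names: tuple = ()
    intercept_index: int | None = None

    @classmethod
    def from_arrays(
        cls,
        subject_ids,
        y,
        X,
        Z=None,
        x_names=None,
        z_names=None,
        intercept_index=None,
    ) -> "LongitudinalDesign":
        """Validate, group rows by subject, and build the design.

        ``Z=None`` uses the random-intercept default (a column of ones).
        """
        subject_ids = np.asarray(subject_ids)
        y = np.asarray(y, dtype=float).ravel()
        X = _as_2d(X, "X")
        N = y.shape[0]
        if subject_ids.shape[0] != N or X.shape[0] != N:
            raise DesignError(
                f"inconsistent row counts: subject_ids {subject_ids.shape[0]}, "
                f"y {N}, X {X.shape[0]}"
            )
        if Z is None:
            Z = np.ones((N, 1))
            z_names = z_names or ("z_intercept",)
        Z = _as_2d(Z, "Z")
        if Z.shape[0] != N:
            raise DesignError(f"Z has {Z.shape[0]} rows, expected {N}")
        if N == 0:
            raise DesignError("empty design: no observations")

        bad = ~np.isin(y, (0.0, 1.0))
        if bad.any():
            r = int(np.flatnonzero(bad)[0])
            raise DesignError(
                f"response must be binary 0/1; row {r} has y={y[bad][0]!r}"
            )
        if (np.abs(X).sum(axis=0) == 0).any():
            j = int(np.flatnonzero(np.abs(X).sum(axis=0) == 0)[0])
            raise DesignError(f"X column {j} is identically zero")

        # stable sort keeps within-subject observation order
        uniq, first_idx = np.unique(subject_ids, return_index=True)
        # preserve order of first appearance rather than sorted label order
        uniq = subject_ids[np.sort(first_idx)]
        pos = {s: k for k, s in enumerate(uniq.tolist())}
        gidx = np.fromiter((pos[s] for s in subject_ids.tolist()), dtype=np.int64, count=N)
        order = np.argsort(gidx, kind="stable")
        gidx = gidx[order]
        starts = np.concatenate([[0], 1 + np.flatnonzero(np.diff(gidx))])

        if x_names is None:
            x_names = tuple(f"x{j + 1}" for j in range(X.shape[1]))
        if z_names is None:
            z_names = tuple(f"z{j + 1}" for j in range(Z.shape[1]))

        return cls(
            subject_ids=subject_ids[order],
            y=y[order],
            X=np.ascontiguousarray(X[order]),
            Z=np.ascontiguousarray(Z[order]),
            group_index=gidx,
            group_starts=starts.astype(np.int64),
            x_names=tuple(x_names),
            z_names=tuple(z_names),
            intercept_index=intercept_index,
        )

    # -- shape accessors -------------------------------------------------
    @property
    def N(self) -> int:
        return self.y.shape[0]

    @property
    def n(self) -> int:
        return self.group_starts.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    @property
    def group_sizes(self) -> np.ndarray:
        return np.diff(np.concatenate([self.group_starts, [self.N]]))

    def group_sum(self, arr: np.ndarray) -> np.ndarray:
        """Sum ``arr`` (axis 0 = rows) within each subject block."""
        return np.add.reduceat(arr, self.group_starts, axis=0)

    def default_penalize_mask(self) -> np.ndarray:
        """All fixed effects penalized except a designated intercept column."""
        mask = np.ones(self.p, dtype=bool)
        if self.intercept_index is not None:
            mask[self.intercept_index] = False
        return mask
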