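"""Reading and writing long-format CSV data.

Expected columns: ``subject``, ``y`` (binary), any number of fixed-effect
columns, and optional ``z_*`` columns for the random-effect design (absent
z columns give the random-intercept default, Z = a column of ones).  An
intercept column is added to X by default and excluded from the ridge
penalty downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import DesignError, LongitudinalDesign

INTERCEPT_NAME = "(intercept)"


def design_from_frame(df: pd.DataFrame, add_intercept: bool = True) -> LongitudinalDesign:
    for col in ("subject", "y"):
        if col not in df.columns:
            raise DesignError(f"missing required column {col!r}")
    if len(df) == 0:
        raise DesignError("empty table: no observations")
    y = pd.to_numeric(df["y"], errors="coerce").to_numpy(dtype=float)
    bad = ~np.isin(y, (0.0, 1.0))
    if bad.any():
        r = int(np.flatnonzero(bad)[0])
        raise DesignError(
            f"non-binary response at row {r}: y={df['y'].iloc[r]!r}"
        )
    z_cols = [c for c in df.columns if c.startswith("z_")]
    x_cols = [c for c in df.columns if c not in ("subject", "y") and c not in z_cols]
    if not x_cols and not add_intercept:
        raise DesignError("no fixed-effect columns found")
    X = df[x_cols].to_numpy(dtype=float) if x_cols else np.empty((len(df), 0))
    x_names = list(x_cols)
    intercept_index = None
    if add_intercept:
        X = np.column_stack([np.ones(len(df)), X])
        x_names = [INTERCEPT_NAME] + x_names
        intercept_index = 0
    Z = df[z_cols].to_numpy(dtype=float) if z_cols else None
    return LongitudinalDesign.from_arrays(
        df["subject"].to_numpy(),
        y,
        X,
        Z,
        x_names=tuple(x_names),
        z_names=tuple(z_cols) if z_cols else None,
        intercept_index=intercept_index,
    )


def read_long_csv(path, add_intercept: bool = True) -> LongitudinalDesign:
    """Load and validate a long-format CSV into a LongitudinalDesign."""
    df = pd.read_csv(path, float_precision="round_trip")
    if len(df) == 0:
        raise DesignError(f"empty file: {path}")
    return design_from_frame(df, add_intercept=add_intercept)


def write_long_csv(design: LongitudinalDesign, path) -> None:
    """Inverse of :func:`read_long_csv` (the intercept column is dropped)."""
    cols = {"subject": design.subject_ids, "y": design.y}
    for j, name in enumerate(design.x_names):
        if j == design.intercept_index:
            continue
        cols[name] = design.X[:, j]
    default_z = design.q == 1 and np.all(design.Z == 1.0)
    if not default_z:
        for j, name in enumerate(design.z_names):
            zname = name if name.startswith("z_") else f"z_{name}"
            cols[zname] = design.Z[:, j]
    df = pd.DataFrame(cols)
    # shortest round-trip representation, bit-exact on re-read
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(lambda v: repr(float(v)))
    df.to_csv(path, index=False)
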