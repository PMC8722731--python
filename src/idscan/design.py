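"""Fixed-effect design construction shared by the diallel and scan models.

Builds the field-trial covariate design: year, progeny type and their
interaction, neighbour-shading deviation, border-row indicators per year,
and fourth-order row/column position polynomials per year.  Covariates that
do not vary in the data are dropped (recorded in the returned names);
aliasing among varying columns raises an error naming the columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _year_dummies(year: np.ndarray, years: list) -> dict[str, np.ndarray]:
    # reference coding: first year absorbed by the intercept
    return {f"year[{y}]": (year == y).astype(float) for y in years[1:]}


def fixed_design(df: pd.DataFrame, include_type: bool = True,
                 extra: dict[str, np.ndarray] | None = None,
                 poly_order: int = 4) -> tuple[np.ndarray, list[str]]:
    """Assemble the fixed design matrix.

    ``extra`` columns (e.g. inbreeding covariates or PC scores) are appended
    after the field covariates.  Returns (X, column names).
    """
    n = len(df)
    year = df["year"].to_numpy()
    years = sorted(pd.unique(year))
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    cols.update(_year_dummies(year, years))
    if include_type and "progeny_type" in df.columns:
        t = (df["progeny_type"].to_numpy() == "selfed").astype(float)
        cols["type[selfed]"] = t
        for y in years[1:]:
            cols[f"type[selfed]:year[{y}]"] = t * (year == y)
    if "shading" in df.columns:
        cols["shading"] = df["shading"].to_numpy(dtype=float)
    if "border" in df.columns:
        b = df["border"].to_numpy(dtype=float)
        for y in years:
            cols[f"border:year[{y}]"] = b * (year == y)
    for axis in ("row", "col"):
        if axis in df.columns:
            x = df[axis].to_numpy(dtype=float)
            for p in range(1, poly_order + 1):
                for y in years:
                    cols[f"{axis}^{p}:year[{y}]"] = (x ** p) * (year == y)
    if extra:
        for name, v in extra.items():
            cols[name] = np.asarray(v, dtype=float)

    # drop non-varying covariates (keep the intercept)
    keep = ["intercept"]
    for name, v in cols.items():
        if name == "intercept":
            continue
        if np.ptp(v) > 0:
            keep.append(name)
    X = np.column_stack([cols[k] for k in keep])

    # rank check among varying columns
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by greedy QR on growing prefixes
        aliased = []
        basis: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, basis + [j]]
            if np.linalg.matrix_rank(trial) > len(basis):
                basis.append(j)
            else:
                aliased.append(keep[j])
        raise ValueError(f"fixed design singular; aliased columns: {aliased}")
    return X, keep
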