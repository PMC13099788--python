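"""Design-matrix construction shared by the regression-based modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import RankError, SchemaError


def encode_terms(
    df: pd.DataFrame, terms: list[str], add_intercept: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Encode a list of column names into a numeric design matrix.

    Categorical/object/bool columns are dummy-coded dropping the first level
    (for ordered categoricals, the first category is the reference). Numeric
    columns enter as-is. Returns the matrix and per-column names.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    if add_intercept:
        blocks.append(np.ones((len(df), 1)))
        names.append("intercept")
    for term in terms:
        if term not in df.columns:
            raise SchemaError(f"design: missing column {term!r}")
        col = df[term]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object or col.dtype == bool:
            dummies = pd.get_dummies(col, prefix=term, drop_first=True, dtype=float)
            blocks.append(dummies.to_numpy())
            names.extend(dummies.columns.tolist())
        else:
            vals = pd.to_numeric(col, errors="raise").to_numpy(dtype=float)[:, None]
            blocks.append(vals)
            names.append(term)
    X = np.hstack(blocks) if blocks else np.empty((len(df), 0))
    return X, names


def check_full_rank(X: np.ndarray, names: list[str], context: str) -> None:
    """Raise :class:`RankError` naming suspect columns if X is rank deficient."""
    if X.shape[1] == 0:
        return
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full column rank
        aliased = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                aliased.append(names[j])
        raise RankError(f"{context}: design is rank deficient; aliased term(s): {aliased}")
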