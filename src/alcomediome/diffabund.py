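"""Differential abundance via per-feature covariate-adjusted linear models.

Pipeline: prevalence filter (fraction of samples with nonzero abundance,
boundary inclusive), optional total-sum scaling, log2 transform with a
pseudo-count, per-feature OLS on exposure + covariates, Benjamini-Hochberg
step-up correction over the feature family, and a mutual-adjustment refit
for selected features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._design import check_full_rank, encode_terms
from .errors import ConfigError, DomainError, UsageError


@dataclass(frozen=True)
class DiffAbundResult:
    feature: str
    log2fc: float
    ci_low: float
    ci_high: float
    p: float
    q: float
    direction: str
    prevalence: float


def prevalence_filter(
    matrix: pd.DataFrame, min_prev: float = 0.1
) -> tuple[pd.DataFrame, list[str]]:
    """Keep features nonzero in at least ``min_prev`` of samples (inclusive).

    Returns the filtered samples x features table and the dropped feature names.
    """
    if not (0 < min_prev <= 1):
        raise ConfigError(f"min_prev must be in (0, 1], got {min_prev}")
    prev = (matrix > 0).mean(axis=0)
    keep = prev >= min_prev
    dropped = matrix.columns[~keep].tolist()
    out = matrix.loc[:, keep]
    if out.shape[1] == 0:
        warnings.warn("prevalence filter removed every feature", stacklevel=2)
    return out, dropped


def default_pseudocount(matrix: pd.DataFrame) -> float:
    """Half the minimum nonzero value in the matrix."""
    vals = matrix.to_numpy(dtype=float)
    nz = vals[vals > 0]
    if nz.size == 0:
        raise DomainError("matrix has no nonzero values; cannot derive a pseudo-count")
    return float(nz.min() / 2.0)


def transform(
    matrix: pd.DataFrame,
    normalization: str = "none",
    pseudo: Optional[float] = None,
) -> pd.DataFrame:
    """Optional TSS normalization followed by y = log2(x + pseudo)."""
    if normalization not in ("none", "tss"):
        raise ConfigError(f"normalization must be 'none' or 'tss', got {normalization!r}")
    x = matrix.to_numpy(dtype=float)
    if np.any(x < 0):
        raise DomainError("abundances must be non-negative")
    if normalization == "tss":
        totals = x.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise DomainError("TSS undefined for samples with zero total")
        x = x / totals
    if pseudo is None:
        nz = x[x > 0]
        if nz.size == 0:
            raise DomainError("matrix has no nonzero values; supply a pseudo-count")
        pseudo = float(nz.min() / 2.0)
    if pseudo <= 0:
        raise ConfigError(f"pseudo-count must be positive, got {pseudo}")
    return pd.DataFrame(np.log2(x + pseudo), index=matrix.index, columns=matrix.columns)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fit_features(
    transformed: pd.DataFrame,
    design: pd.DataFrame,
    exposure: str,
    covariates: Sequence[str] = (),
    prevalence: Optional[pd.Series] = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-feature OLS of transformed abundance on exposure + covariates.

    The exposure may be continuous or binary; its coefficient is reported as
    log2 fold change per exposure unit. BH correction runs over all features
    fitted for this exposure. Constant features are skipped and returned in
    the second element. ``prevalence`` (per-feature nonzero fraction from the
    untransformed matrix) is carried through when provided; otherwise the
    fraction of values above the per-feature minimum is used as a proxy.

    Returns ``(results, skipped)`` where ``results`` has one row per feature
    with the :class:`DiffAbundResult` fields.
    """
    if len(design) != len(transformed):
        raise DomainError("design and abundance tables have different numbers of samples")
    X, names = encode_terms(design, [exposure, *covariates])
    check_full_rank(X, names, "fit_features")
    exp_cols = [j for j, nm in enumerate(names) if nm == exposure or nm.startswith(exposure + "_")]
    if len(exp_cols) != 1:
        raise UsageError(
            f"exposure {exposure!r} must encode to exactly one design column, got {len(exp_cols)}"
        )
    j = exp_cols[0]
    y = transformed.to_numpy(dtype=float)
    variances = y.var(axis=0)
    active = variances > 0
    skipped = transformed.columns[~active].tolist()
    y = y[:, active]
    feats = transformed.columns[active]
    n, k = X.shape
    df_resid = n - k
    if df_resid <= 0:
        raise UsageError("not enough samples for the requested design")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y  # k x features
    resid = y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df_resid
    se = np.sqrt(xtx_inv[j, j] * sigma2)
    b = beta[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, b / se, np.inf * np.sign(b))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    tcrit = stats.t.ppf(0.975, df_resid)
    qvals = bh_adjust(pvals)
    if prevalence is not None:
        prev = prevalence.reindex(feats).to_numpy(dtype=float)
    else:
        yv = transformed.loc[:, feats].to_numpy()
        prev = (yv > yv.min(axis=0)).mean(axis=0)
    res = pd.DataFrame(
        {
            "feature": feats,
            "log2fc": b,
            "ci_low": b - tcrit * se,
            "ci_high": b + tcrit * se,
            "p": pvals,
            "q": qvals,
            "direction": np.where(b >= 0, "positive", "negative"),
            "prevalence": prev,
        }
    ).reset_index(drop=True)
    return res, skipped


def mutual_adjustment(
    transformed: pd.DataFrame,
    selected: Sequence[str],
    design: pd.DataFrame,
    exposure: str,
    covariates: Sequence[str] = (),
    alpha: float = 0.05,
    ridge: float = 1e-8,
) -> pd.DataFrame:
    """Refit each selected feature adjusting for the other selected features.

    Each refit adds the remaining selected features' transformed abundances
    as covariates. Near-singular designs are ridge-stabilized with a warning.
    Returns one row per feature with the refit exposure coefficient, p-value
    and a ``retained`` flag (p < alpha).
    """
    selected = list(selected)
    if len(selected) < 2:
        raise UsageError("mutual adjustment needs at least two selected features")
    missing = [f for f in selected if f not in transformed.columns]
    if missing:
        raise UsageError(f"selected feature(s) not in matrix: {missing}")
    X_base, names = encode_terms(design, [exposure, *covariates])
    j = names.index(exposure) if exposure in names else None
    if j is None:
        cand = [i for i, nm in enumerate(names) if nm.startswith(exposure + "_")]
        if len(cand) != 1:
            raise UsageError(f"exposure {exposure!r} must encode to one column")
        j = cand[0]
    n = X_base.shape[0]
    rows = []
    for feat in selected:
        others = [f for f in selected if f != feat]
        X = np.hstack([X_base, transformed[others].to_numpy(dtype=float)])
        y = transformed[feat].to_numpy(dtype=float)
        xtx = X.T @ X
        cond = np.linalg.cond(xtx)
        if cond > 1e12:
            warnings.warn(
                f"mutual_adjustment: near-collinear design for {feat}; ridge-stabilizing",
                stacklevel=2,
            )
            xtx = xtx + ridge * np.trace(xtx) / xtx.shape[0] * np.eye(xtx.shape[0])
        xtx_inv = np.linalg.inv(xtx)
        beta = xtx_inv @ X.T @ y
        resid = y - X @ beta
        df_resid = n - X.shape[1]
        if df_resid <= 0:
            raise UsageError("not enough samples for mutual adjustment")
        sigma2 = resid @ resid / df_resid
        se = np.sqrt(xtx_inv[j, j] * sigma2)
        tval = beta[j] / se if se > 0 else np.inf
        p = 2.0 * stats.t.sf(abs(tval), df_resid)
        rows.append(
            {
                "feature": feat,
                "log2fc": beta[j],
                "p": p,
                "retained": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)
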