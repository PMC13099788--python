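"""Alpha/beta diversity analytics.

Alpha diversity: Shannon entropy H = -sum p_i log p_i (natural log by
default) and the inverse Simpson index D = 1 / sum p_i^2, with
covariate-adjusted regressions on the log index reported as percent
differences. Beta diversity: Bray-Curtis dissimilarities, principal
coordinates, covariate-adjusted PERMANOVA (marginal sums of squares with
Freedman-Lane residual permutation) with partial omega-squared effect
sizes, and group-dispersion comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform

from ._design import check_full_rank, encode_terms
from .errors import DomainError, UsageError


@dataclass(frozen=True)
class AlphaDiversity:
    shannon: float
    inv_simpson: float
    richness: int


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise DomainError("distance matrix must be square")
        if len(self.labels) != d.shape[0]:
            raise DomainError("label count does not match matrix size")
        if not np.allclose(d, d.T, atol=1e-12):
            raise DomainError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise DomainError("distance matrix must have zero diagonal")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PermanovaResult:
    term: str
    ss: float
    df: int
    pseudo_f: float
    omega_sq: float
    p_perm: float
    n_perm: int
    ss_total: float = field(default=np.nan)
    ss_resid: float = field(default=np.nan)
    df_resid: int = field(default=0)


def alpha_diversity(sample: Sequence[float], log_base: float | None = None) -> AlphaDiversity:
    """Shannon (nats by default), inverse Simpson and richness for one sample.

    The vector is renormalized to proportions internally; zero entries
    contribute nothing to H.
    """
    x = np.asarray(sample, dtype=float)
    if np.any(x < 0):
        raise DomainError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise DomainError("all-zero abundance vector has undefined diversity")
    p = x / total
    nz = p[p > 0]
    shannon = float(-(nz * np.log(nz)).sum())
    if log_base is not None:
        shannon /= np.log(log_base)
    inv_simpson = float(1.0 / (nz**2).sum())
    return AlphaDiversity(shannon=shannon, inv_simpson=inv_simpson, richness=int(nz.size))


def alpha_diversity_frame(matrix: pd.DataFrame, log_base: float | None = None) -> pd.DataFrame:
    """Per-sample alpha indices for a samples x features table."""
    rows = {
        sid: alpha_diversity(matrix.loc[sid].to_numpy(), log_base=log_base)
        for sid in matrix.index
    }
    return pd.DataFrame(
        {
            "shannon": {k: v.shannon for k, v in rows.items()},
            "inv_simpson": {k: v.inv_simpson for k, v in rows.items()},
            "richness": {k: v.richness for k, v in rows.items()},
        }
    ).loc[matrix.index]


def alpha_regression(
    alpha: pd.Series,
    design: pd.DataFrame,
    exposure: str,
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """OLS of ln(index) on exposure + covariates, reported as percent differences.

    Coefficients b are mapped to 100*(exp(b)-1) percent difference per
    exposure unit, with delta-free CI endpoints mapped the same way.
    """
    vals = alpha.to_numpy(dtype=float)
    if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
        raise DomainError("alpha indices must be strictly positive for log regression")
    X, names = encode_terms(design, [exposure, *covariates])
    check_full_rank(X, names, "alpha_regression")
    fit = sm.OLS(np.log(vals), X).fit()
    conf = fit.conf_int()
    rows = []
    for j, name in enumerate(names):
        if not name.startswith(exposure):
            continue
        rows.append(
            {
                "term": name,
                "pct_diff": 100.0 * (np.exp(fit.params[j]) - 1.0),
                "ci_low": 100.0 * (np.exp(conf[j, 0]) - 1.0),
                "ci_high": 100.0 * (np.exp(conf[j, 1]) - 1.0),
                "p": float(fit.pvalues[j]),
            }
        )
    return pd.DataFrame(rows)


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities for a samples x features table."""
    x = matrix.to_numpy(dtype=float)
    if np.any(x < 0):
        raise DomainError("abundances must be non-negative")
    totals = x.sum(axis=1)
    if np.any(totals <= 0):
        bad = [str(matrix.index[i]) for i in np.flatnonzero(totals <= 0)]
        raise DomainError(f"sample(s) with zero total abundance: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(labels=tuple(matrix.index), values=d)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def pcoa(dm: DistanceMatrix, k: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate (classical MDS) embedding.

    Returns ``(coordinates, eigenvalues)`` where eigenvalues are all n of
    them, sorted descending — negative ones are reported as-is, never
    corrected. Coordinates span the top-k positive-eigenvalue axes.
    """
    n = dm.n
    if k is None:
        k = n - 1
    if k > n - 1 or k < 1:
        raise UsageError(f"k must be in [1, n-1]; got k={k}, n={n}")
    g = _gower_center(dm.values)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = np.clip(eigvals[:k], 0.0, None)
    coords = eigvecs[:, :k] * np.sqrt(pos)
    return coords, eigvals


def _hat(x: np.ndarray) -> np.ndarray:
    # pseudo-inverse based projection is safe for rank-checked designs
    return x @ np.linalg.pinv(x)


def permanova(
    dm: DistanceMatrix,
    design: pd.DataFrame,
    term: str,
    covariates: Sequence[str] = (),
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Distance-based multivariate ANOVA for one term, adjusting for covariates.

    Marginal sums of squares are computed from trace forms of the
    Gower-centered matrix; the permutation p-value permutes reduced-model
    residuals (Freedman-Lane). The permutation seed is required and logged
    in the result via the arguments.
    """
    if len(design) != dm.n:
        raise DomainError("design rows do not match distance matrix size")
    if seed is None:
        raise UsageError("permanova requires an explicit permutation seed")
    g = _gower_center(dm.values)
    xz, z_names = encode_terms(design, list(covariates))
    x_full, full_names = encode_terms(design, [*covariates, term])
    check_full_rank(x_full, full_names, f"permanova({term})")
    n = dm.n
    h_full = _hat(x_full)
    h_red = _hat(xz)
    rank_full = int(np.linalg.matrix_rank(x_full))
    rank_red = int(np.linalg.matrix_rank(xz))
    df_term = rank_full - rank_red
    if df_term < 1:
        raise UsageError(f"term {term!r} adds no columns beyond the covariates")
    df_resid = n - rank_full
    m_num = h_full - h_red
    m_den = np.eye(n) - h_full
    ss_term = float(np.sum(m_num * g))
    ss_resid = float(np.sum(m_den * g))
    ss_total = float(np.trace(g))
    ms_resid = ss_resid / df_resid
    pseudo_f = (ss_term / df_term) / ms_resid
    omega_sq = (ss_term - df_term * ms_resid) / (ss_total + ms_resid)

    # Freedman-Lane: permute rows/cols of the reduced-model residualized Gower matrix
    r = np.eye(n) - h_red
    g_res = r @ g @ r
    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(n_perm):
        ix = rng.permutation(n)
        gp = g_res[np.ix_(ix, ix)]
        num = np.sum(m_num * gp) / df_term
        den = np.sum(m_den * gp) / df_resid
        if num / den >= pseudo_f - 1e-12:
            count += 1
    p_perm = count / (n_perm + 1)
    return PermanovaResult(
        term=term,
        ss=ss_term,
        df=df_term,
        pseudo_f=pseudo_f,
        omega_sq=omega_sq,
        p_perm=p_perm,
        n_perm=n_perm,
        ss_total=ss_total,
        ss_resid=ss_resid,
        df_resid=df_resid,
    )


def dispersion(
    dm: DistanceMatrix,
    groups: pd.Series | Sequence,
    reference: Optional[str] = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-group median distance to the group centroid, with permutation p-values.

    Centroids live in the positive-eigenvalue PCoA space. Each non-reference
    group is compared to the reference by the absolute difference in median
    distances, permuting sample-to-group labels between the two groups.
    """
    groups = pd.Series(list(groups))
    counts = groups.value_counts()
    if len(counts) < 2:
        raise UsageError("dispersion requires at least two groups")
    if (counts < 2).any():
        singles = counts[counts < 2].index.tolist()
        raise UsageError(f"singleton group(s) not allowed: {singles}")
    rng = np.random.default_rng(seed)
    coords, eigvals = pcoa(dm, k=dm.n - 1)
    coords = coords[:, : max(1, int((eigvals > 1e-10).sum()))]
    dist_to_centroid = np.empty(dm.n)
    for gname in counts.index:
        mask = (groups == gname).to_numpy()
        centroid = coords[mask].mean(axis=0)
        dist_to_centroid[mask] = np.linalg.norm(coords[mask] - centroid, axis=1)
    if reference is None:
        reference = counts.index[0]
    ref_mask = (groups == reference).to_numpy()
    rows = []
    for gname in counts.index:
        mask = (groups == gname).to_numpy()
        med = float(np.median(dist_to_centroid[mask]))
        if gname == reference:
            rows.append({"group": gname, "n": int(mask.sum()), "median_dist": med, "p_perm": np.nan})
            continue
        pooled = dist_to_centroid[mask | ref_mask]
        n_g = int(mask.sum())
        stat = abs(med - np.median(dist_to_centroid[ref_mask]))
        count = 1
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(np.median(perm[:n_g]) - np.median(perm[n_g:])) >= stat - 1e-15:
                count += 1
        rows.append(
            {
                "group": gname,
                "n": n_g,
                "median_dist": med,
                "p_perm": count / (n_perm + 1),
            }
        )
    return pd.DataFrame(rows)
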