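"""Cross-validated log-ratio microbial score.

The score for a sample is log((sum of abundances over the "elevated" taxon
set + pseudo) / (sum over the "depleted" set + pseudo)) — a single shared
pseudo-count added to each summed side (a per-taxon variant is available by
flag). Taxon sets are selected by differential abundance against the
exposure inside a k-fold cross-validation so that no sample's score uses
taxa selected with its own data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import diffabund
from .errors import AlignmentError, DomainError, UsageError


@dataclass
class FoldSelection:
    fold: int
    taxa_pos: list[str]
    taxa_neg: list[str]
    fallback_used: bool = False
    notes: str = ""


@dataclass
class ScoreResult:
    """Per-sample scores plus the per-fold taxon sets that produced them."""

    table: pd.DataFrame  # sample_id, score, fold
    folds: list[FoldSelection] = field(default_factory=list)

    def fold_sets(self) -> dict[int, dict[str, list[str]]]:
        return {
            f.fold: {"taxa_pos": f.taxa_pos, "taxa_neg": f.taxa_neg, "fallback": f.fallback_used}
            for f in self.folds
        }


def gevers_score(
    abundances: pd.DataFrame | pd.Series,
    taxa_pos: Sequence[str],
    taxa_neg: Sequence[str],
    pseudo: float,
    log_base: Optional[float] = None,
    per_taxon_pseudo: bool = False,
) -> np.ndarray | float:
    """Log-ratio of summed elevated vs depleted taxon abundances.

    Natural log by default. With ``per_taxon_pseudo`` the pseudo-count is
    added to every taxon before summation instead of once per side.
    """
    taxa_pos, taxa_neg = list(taxa_pos), list(taxa_neg)
    if not taxa_pos or not taxa_neg:
        raise DomainError("both taxon sets must be non-empty")
    if set(taxa_pos) & set(taxa_neg):
        raise DomainError("taxon sets must be disjoint")
    if pseudo <= 0:
        raise DomainError(f"pseudo-count must be positive, got {pseudo}")
    single = isinstance(abundances, pd.Series)
    mat = abundances.to_frame().T if single else abundances
    missing = [t for t in taxa_pos + taxa_neg if t not in mat.columns]
    if missing:
        raise DomainError(f"taxa not present in abundance table: {missing}")
    pos = mat[taxa_pos].to_numpy(dtype=float)
    neg = mat[taxa_neg].to_numpy(dtype=float)
    if per_taxon_pseudo:
        num = (pos + pseudo).sum(axis=1)
        den = (neg + pseudo).sum(axis=1)
    else:
        num = pos.sum(axis=1) + pseudo
        den = neg.sum(axis=1) + pseudo
    score = np.log(num / den)
    if log_base is not None:
        score = score / np.log(log_base)
    return float(score[0]) if single else score


def assign_folds(
    n: int, k: int, seed: int, strata: Optional[Sequence] = None
) -> np.ndarray:
    """Seeded fold assignment in 1..k, optionally stratified."""
    if k < 2 or k > n:
        raise UsageError(f"k must be in [2, n]; got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    folds = np.zeros(n, dtype=int)
    if strata is None:
        strata = np.zeros(n, dtype=int)
    strata = np.asarray(pd.Series(list(strata)).astype(str))
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        folds[idx] = (np.arange(idx.size) % k) + 1
    return folds


def select_taxa(
    results: pd.DataFrame,
    q_select: float = 0.05,
    fallback_m: int = 5,
) -> tuple[list[str], list[str], bool]:
    """Split q-significant features by direction; fall back to top-m by p per direction."""
    sig = results[results["q"] < q_select]
    pos = sig.loc[sig["direction"] == "positive", "feature"].tolist()
    neg = sig.loc[sig["direction"] == "negative", "feature"].tolist()
    fallback = False
    if not pos or not neg:
        fallback = True
        by_p = results.sort_values("p", kind="stable")
        if not pos:
            pos = by_p.loc[by_p["direction"] == "positive", "feature"].head(fallback_m).tolist()
        if not neg:
            neg = by_p.loc[by_p["direction"] == "negative", "feature"].head(fallback_m).tolist()
    return pos, neg, fallback


def cv_score(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    exposure: str,
    covariates: Sequence[str] = (),
    outcome: Optional[pd.Series] = None,
    k: int = 5,
    q_select: float = 0.05,
    fallback_m: int = 5,
    min_prev: float = 0.1,
    pseudo: Optional[float] = None,
    seed: int = 0,
) -> ScoreResult:
    """Cross-validated log-ratio score.

    Samples are partitioned into ``k`` seeded folds (stratified by
    ``outcome`` when given). For each fold, differential abundance runs on
    the other folds only; selected taxa are split by direction and the
    held-out samples are scored with them, so no participant's score derives
    from their own data. Folds where a direction selects nothing fall back
    to the top ``fallback_m`` features by p-value in that direction (flagged).
    """
    n = len(matrix)
    if len(design) != n:
        raise AlignmentError("design and abundance tables have different numbers of samples")
    if outcome is not None and len(outcome) != n:
        raise AlignmentError("outcome not aligned with abundance table")
    if n < 2 * k and k != n:  # k == n is leave-one-out, explicitly allowed
        raise UsageError(f"need n >= 2k for {k}-fold CV (or k == n); got n={n}")
    filtered, _ = diffabund.prevalence_filter(matrix, min_prev=min_prev)
    if pseudo is None:
        pseudo = diffabund.default_pseudocount(filtered)
    transformed = diffabund.transform(filtered, normalization="none", pseudo=pseudo)
    prevalence = (filtered > 0).mean(axis=0)
    folds = assign_folds(n, k, seed=seed, strata=outcome)
    scores = np.full(n, np.nan)
    fold_info: list[FoldSelection] = []
    for f in sorted(np.unique(folds)):
        train = folds != f
        test = ~train
        res, _ = diffabund.fit_features(
            transformed.loc[train],
            design.loc[train],
            exposure,
            covariates,
            prevalence=prevalence,
        )
        pos, neg, fb = select_taxa(res, q_select=q_select, fallback_m=fallback_m)
        fold_info.append(FoldSelection(fold=int(f), taxa_pos=pos, taxa_neg=neg, fallback_used=fb))
        scores[test] = gevers_score(filtered.loc[test], pos, neg, pseudo=pseudo)
    table = pd.DataFrame(
        {"sample_id": matrix.index, "score": scores, "fold": folds}
    ).reset_index(drop=True)
    return ScoreResult(table=table, folds=fold_info)


def full_data_score(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    exposure: str,
    covariates: Sequence[str] = (),
    q_select: float = 0.05,
    fallback_m: int = 5,
    min_prev: float = 0.1,
    pseudo: Optional[float] = None,
) -> ScoreResult:
    """Non-cross-validated variant: selects taxa on all samples, then scores all.

    Exists to quantify the selection-leakage bias the CV construction avoids.
    """
    filtered, _ = diffabund.prevalence_filter(matrix, min_prev=min_prev)
    if pseudo is None:
        pseudo = diffabund.default_pseudocount(filtered)
    transformed = diffabund.transform(filtered, normalization="none", pseudo=pseudo)
    prevalence = (filtered > 0).mean(axis=0)
    res, _ = diffabund.fit_features(transformed, design, exposure, covariates, prevalence=prevalence)
    pos, neg, fb = select_taxa(res, q_select=q_select, fallback_m=fallback_m)
    scores = gevers_score(filtered, pos, neg, pseudo=pseudo)
    table = pd.DataFrame(
        {"sample_id": matrix.index, "score": scores, "fold": 0}
    ).reset_index(drop=True)
    return ScoreResult(
        table=table, folds=[FoldSelection(fold=0, taxa_pos=pos, taxa_neg=neg, fallback_used=fb)]
    )
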