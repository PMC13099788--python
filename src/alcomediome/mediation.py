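"""Counterfactual mediation decomposition on the risk-difference scale.

The mediator model is a homoscedastic normal linear regression of the score
on log2 alcohol + covariates; the outcome model is a logistic regression of
the advanced-lesion indicator on alcohol, score and covariates (no
exposure-mediator interaction). For a contrast (a0, a1 = a0 + delta) on the
log2-alcohol scale — delta = 1 is a twofold intake increase — counterfactual
mediator values M(a) ~ Normal(fitted mean at a, residual SD) are pushed
through the outcome model to give potential-outcome probabilities
Y(a, M(a')). ACME and ADE average the a0- and a1-referenced variants, so
total = ACME + ADE holds exactly; proportion mediated = ACME / total.
Percentile bootstrap CIs resample participants and refit everything.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._design import check_full_rank, encode_terms
from .errors import DomainError, UsageError

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(21)


@dataclass
class MediatorFit:
    params: pd.Series
    covariance: np.ndarray
    sigma: float
    exposure: str
    covariates: list[str]
    names: list[str]
    n: int


@dataclass
class OutcomeFit:
    params: pd.Series
    covariance: np.ndarray
    exposure: str
    mediator: str
    covariates: list[str]
    names: list[str]
    n: int
    converged: bool


@dataclass
class MediationResult:
    total_effect: float
    ade: float
    acme: float
    prop_mediated: float
    pm_defined: bool
    ci_total: tuple[float, float]
    ci_ade: tuple[float, float]
    ci_acme: tuple[float, float]
    ci_prop: tuple[float, float]
    n_boot: int
    contrast: tuple[str, float]
    seed: Optional[int]
    n_failed: int = 0


def fit_mediator_model(
    data: pd.DataFrame,
    score_col: str,
    exposure_col: str,
    covariates: Sequence[str] = (),
) -> MediatorFit:
    """OLS of the microbial score on exposure + covariates; residual SD retained."""
    y = data[score_col].to_numpy(dtype=float)
    if np.var(y) == 0:
        raise DomainError("mediator (score) has zero variance")
    X, names = encode_terms(data, [exposure_col, *covariates])
    check_full_rank(X, names, "fit_mediator_model")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = X.shape[0] - X.shape[1]
    if df_resid <= 0:
        raise UsageError("not enough rows to fit the mediator model")
    sigma2 = resid @ resid / df_resid
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return MediatorFit(
        params=pd.Series(beta, index=names),
        covariance=cov,
        sigma=float(np.sqrt(sigma2)),
        exposure=exposure_col,
        covariates=list(covariates),
        names=names,
        n=X.shape[0],
    )


def _logit_newton(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        p = expit(X @ beta)
        grad = X.T @ (y - p)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = np.clip(p * (1 - p), 1e-10, None)
        info = X.T @ (w[:, None] * X)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(info + 1e-8 * np.eye(X.shape[1]), grad)
        # cap runaway steps (separation)
        norm = np.linalg.norm(step)
        if norm > 50:
            step *= 50 / norm
        beta = beta + step
    p = expit(X @ beta)
    w = np.clip(p * (1 - p), 1e-10, None)
    info = X.T @ (w[:, None] * X)
    cov = np.linalg.inv(info + (0 if converged else 1e-8) * np.eye(X.shape[1]))
    return beta, cov, converged


def fit_outcome_model(
    data: pd.DataFrame,
    outcome_col: str,
    exposure_col: str,
    score_col: str,
    covariates: Sequence[str] = (),
) -> OutcomeFit:
    """ML logistic regression of the binary outcome on exposure + mediator + covariates."""
    y = data[outcome_col].to_numpy()
    uniq = np.unique(y)
    if not np.isin(uniq, [0, 1]).all() or uniq.size != 2:
        raise UsageError(
            f"outcome {outcome_col!r} must be binary 0/1 with both classes present, got {uniq}"
        )
    y = y.astype(float)
    X, names = encode_terms(data, [exposure_col, score_col, *covariates])
    check_full_rank(X, names, "fit_outcome_model")
    beta, cov, converged = _logit_newton(X, y)
    return OutcomeFit(
        params=pd.Series(beta, index=names),
        covariance=cov,
        exposure=exposure_col,
        mediator=score_col,
        covariates=list(covariates),
        names=names,
        n=X.shape[0],
        converged=converged,
    )


def _potential_probs(
    med_fit: MediatorFit,
    out_fit: OutcomeFit,
    data: pd.DataFrame,
    delta: float,
    n_sim: Optional[int],
    rng: Optional[np.random.Generator],
) -> dict[tuple[int, int], np.ndarray]:
    """Per-participant P(a, a') for a, a' in {a0 (observed), a1 = a0 + delta}."""
    Xm, names_m = encode_terms(data, [med_fit.exposure, *med_fit.covariates])
    if names_m != med_fit.names:
        raise UsageError("data does not encode to the mediator model's design columns")
    mu0 = Xm @ med_fit.params.to_numpy()
    b_exp_m = med_fit.params[med_fit.exposure]
    mu1 = mu0 + b_exp_m * delta

    Xo, names_o = encode_terms(data, [out_fit.exposure, out_fit.mediator, *out_fit.covariates])
    if names_o != out_fit.names:
        raise UsageError("data does not encode to the outcome model's design columns")
    gamma = out_fit.params[out_fit.mediator]
    b_exp_o = out_fit.params[out_fit.exposure]
    eta0 = Xo @ out_fit.params.to_numpy() - gamma * data[out_fit.mediator].to_numpy(dtype=float)
    eta1 = eta0 + b_exp_o * delta
    sigma = med_fit.sigma

    def integrate(eta: np.ndarray, mu: np.ndarray) -> np.ndarray:
        if n_sim is None:  # Gauss-Hermite quadrature, deterministic
            vals = expit(eta[:, None] + gamma * (mu[:, None] + np.sqrt(2) * sigma * _GH_NODES))
            return vals @ _GH_WEIGHTS / np.sqrt(np.pi)
        z = rng.standard_normal(n_sim)
        vals = expit(eta[:, None] + gamma * (mu[:, None] + sigma * z))
        return vals.mean(axis=1)

    probs = {}
    for ai, eta in ((0, eta0), (1, eta1)):
        for mi, mu in ((0, mu0), (1, mu1)):
            probs[(ai, mi)] = integrate(eta, mu)
    return probs


def decompose(
    med_fit: MediatorFit,
    out_fit: OutcomeFit,
    data: pd.DataFrame,
    delta: float = 1.0,
    n_sim: Optional[int] = 1000,
    seed: Optional[int] = None,
) -> dict:
    """Point estimates of total effect, ADE, ACME and proportion mediated.

    ``n_sim`` draws simulate the counterfactual mediator; ``n_sim=None``
    switches to deterministic Gauss-Hermite quadrature (used inside the
    bootstrap). The a0- and a1-referenced effect variants are averaged.
    """
    rng = np.random.default_rng(seed) if n_sim is not None else None
    p = _potential_probs(med_fit, out_fit, data, delta, n_sim, rng)
    acme = 0.5 * float(np.mean(p[(1, 1)] - p[(1, 0)]) + np.mean(p[(0, 1)] - p[(0, 0)]))
    ade = 0.5 * float(np.mean(p[(1, 0)] - p[(0, 0)]) + np.mean(p[(1, 1)] - p[(0, 1)]))
    total = float(np.mean(p[(1, 1)] - p[(0, 0)]))
    pm_defined = abs(total) > 1e-12
    pm = acme / total if pm_defined else np.nan
    return {
        "acme": acme,
        "ade": ade,
        "total_effect": total,
        "prop_mediated": pm,
        "pm_defined": pm_defined,
    }


def bootstrap(
    data: pd.DataFrame,
    score_col: str,
    exposure_col: str,
    outcome_col: str,
    covariates_mediator: Sequence[str] = (),
    covariates_outcome: Sequence[str] = (),
    delta: float = 1.0,
    n_boot: int = 1000,
    n_sim: Optional[int] = 1000,
    seed: int = 0,
    max_failure_frac: float = 0.1,
) -> MediationResult:
    """Nonparametric percentile bootstrap of the mediation decomposition.

    Participants are resampled with replacement; both models are refit and
    the decomposition recomputed per replicate (quadrature integration, which
    is deterministic given the refit). 2.5/97.5 percentiles give the CIs.
    Aborts if more than ``max_failure_frac`` of replicates fail to fit.
    """
    if n_boot < 100:
        raise UsageError("n_boot must be at least 100 for CI output")
    med = fit_mediator_model(data, score_col, exposure_col, covariates_mediator)
    out = fit_outcome_model(data, outcome_col, exposure_col, score_col, covariates_outcome)
    point = decompose(med, out, data, delta=delta, n_sim=n_sim, seed=seed)
    rng = np.random.default_rng(seed)
    n = len(data)
    draws = {"total_effect": [], "ade": [], "acme": [], "prop_mediated": []}
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = data.iloc[idx].reset_index(drop=True)
        try:
            med_b = fit_mediator_model(boot, score_col, exposure_col, covariates_mediator)
            out_b = fit_outcome_model(boot, outcome_col, exposure_col, score_col, covariates_outcome)
            if not out_b.converged:
                raise RuntimeError("outcome model did not converge")
            est = decompose(med_b, out_b, boot, delta=delta, n_sim=None)
        except Exception:
            n_failed += 1
            continue
        for key in draws:
            draws[key].append(est[key])
    if n_failed > max_failure_frac * n_boot:
        raise RuntimeError(
            f"bootstrap aborted: {n_failed}/{n_boot} replicates failed to fit "
            "(possible separation or rank deficiency)"
        )

    def pct_ci(vals):
        arr = np.asarray([v for v in vals if np.isfinite(v)])
        if arr.size == 0:
            return (np.nan, np.nan)
        return (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))

    return MediationResult(
        total_effect=point["total_effect"],
        ade=point["ade"],
        acme=point["acme"],
        prop_mediated=point["prop_mediated"],
        pm_defined=point["pm_defined"],
        ci_total=pct_ci(draws["total_effect"]),
        ci_ade=pct_ci(draws["ade"]),
        ci_acme=pct_ci(draws["acme"]),
        ci_prop=pct_ci(draws["prop_mediated"]),
        n_boot=n_boot,
        contrast=("observed", delta),
        seed=seed,
        n_failed=n_failed,
    )
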