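"""Multinomial logistic association models for screening outcomes.

Fits the K-category baseline-logit model by Newton iteration on the
multinomial log-likelihood (analytic gradient and observed information,
ridge fallback 1e-8 on singular information, gradient-norm tolerance 1e-8),
with Wald CIs from the inverse observed information. Provides odds-ratio
tables, ordinal trend tests and Wald interaction tests, plus the exposure
codings used throughout: categorical level, per-10 g/day, per-twofold
(log2(g+1)), guideline adherence and consumer vs non-consumer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._design import check_full_rank, encode_terms
from .errors import UsageError

CODINGS = ("categorical", "per_10g", "per_twofold", "adherence", "consumer_vs_non")

#: design column(s) produced by each exposure coding (see exposure.classify_exposure_frame)
CODING_TERMS = {
    "categorical": ["alcohol_level"],
    "per_10g": ["alcohol_per10g"],
    "per_twofold": ["log2_alcohol"],
    "adherence": ["adherence"],
    "consumer_vs_non": ["consumer"],
}


@dataclass
class MultinomFit:
    """Baseline-logit multinomial fit; rows of ``coefficients`` are the non-reference contrasts."""

    coefficients: pd.DataFrame  # (K-1) x p, index = outcome labels, columns = term names
    covariance: np.ndarray  # ((K-1)p) x ((K-1)p), contrast-major flattening
    n: int
    reference_outcome: str
    converged: bool
    loglike: float

    @property
    def term_names(self) -> list[str]:
        return list(self.coefficients.columns)

    @property
    def outcome_labels(self) -> list[str]:
        return list(self.coefficients.index)

    def se(self) -> pd.DataFrame:
        k1, p = self.coefficients.shape
        return pd.DataFrame(
            np.sqrt(np.diag(self.covariance)).reshape(k1, p),
            index=self.coefficients.index,
            columns=self.coefficients.columns,
        )

    def flat_index(self, outcome: str, term: str) -> int:
        c = self.outcome_labels.index(outcome)
        j = self.term_names.index(term)
        return c * len(self.term_names) + j


def _softmax_baseline(eta: np.ndarray) -> np.ndarray:
    """P(category c | x) for non-reference categories; reference has eta = 0."""
    m = np.maximum(eta.max(axis=1, keepdims=True), 0.0)
    ex = np.exp(eta - m)
    denom = np.exp(-m) + ex.sum(axis=1, keepdims=True)
    return ex / denom


def fit_multinomial(
    design: pd.DataFrame,
    outcome: pd.Series | Sequence,
    terms: Sequence[str],
    reference: Optional[str] = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    ridge: float = 1e-8,
) -> MultinomFit:
    """Maximum-likelihood multinomial (baseline-category) logistic regression.

    ``reference`` defaults to the first outcome level in sorted order. Every
    declared outcome level must be observed; an empty category is an error,
    never a degenerate fit. Non-convergence yields ``converged=False``.
    """
    y = pd.Series(list(outcome)).astype(str)
    levels = sorted(y.unique())
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise UsageError(f"reference outcome {reference!r} not present in data")
    counts = y.value_counts()
    if (counts == 0).any() or len(levels) < 2:
        raise UsageError("every outcome category must be non-empty and at least two required")
    contrasts = [lv for lv in levels if lv != reference]
    X, names = encode_terms(design, list(terms))
    check_full_rank(X, names, "fit_multinomial")
    n, p = X.shape
    k1 = len(contrasts)
    Y = np.column_stack([(y == lv).to_numpy(float) for lv in contrasts])

    b = np.zeros((k1, p))
    ll_prev = -np.inf
    converged = False
    info = np.eye(k1 * p)
    for _ in range(max_iter):
        eta = X @ b.T
        P = _softmax_baseline(eta)
        # log-likelihood
        ref_p = 1.0 - P.sum(axis=1)
        ll = float(np.sum(Y * eta) + np.sum(np.log(np.clip(ref_p, 1e-300, None))))
        grad = (X.T @ (Y - P)).T.reshape(-1)  # contrast-major
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        # observed information, block (c, d) = X' diag(P_c (delta_cd - P_d)) X
        info = np.empty((k1 * p, k1 * p))
        for c in range(k1):
            for d in range(k1):
                w = P[:, c] * ((1.0 - P[:, d]) if c == d else -P[:, d])
                info[c * p : (c + 1) * p, d * p : (d + 1) * p] = X.T @ (w[:, None] * X)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(info + ridge * np.eye(k1 * p), grad)
        # step-halving to guarantee likelihood ascent
        scale = 1.0
        b_new = b + scale * step.reshape(k1, p)
        for _half in range(30):
            eta_new = X @ b_new.T
            P_new = _softmax_baseline(eta_new)
            ref_new = 1.0 - P_new.sum(axis=1)
            ll_new = float(np.sum(Y * eta_new) + np.sum(np.log(np.clip(ref_new, 1e-300, None))))
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
            b_new = b + scale * step.reshape(k1, p)
        b = b_new
        ll_prev = ll
    eta = X @ b.T
    P = _softmax_baseline(eta)
    ref_p = 1.0 - P.sum(axis=1)
    ll = float(np.sum(Y * eta) + np.sum(np.log(np.clip(ref_p, 1e-300, None))))
    info = np.empty((k1 * p, k1 * p))
    for c in range(k1):
        for d in range(k1):
            w = P[:, c] * ((1.0 - P[:, d]) if c == d else -P[:, d])
            info[c * p : (c + 1) * p, d * p : (d + 1) * p] = X.T @ (w[:, None] * X)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.inv(info + ridge * np.eye(k1 * p))
        converged = False
    coef = pd.DataFrame(b, index=contrasts, columns=names)
    return MultinomFit(
        coefficients=coef,
        covariance=cov,
        n=n,
        reference_outcome=reference,
        converged=converged,
        loglike=ll,
    )


def odds_ratio_table(fit: MultinomFit, terms: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-term, per-outcome ORs with Wald 95% CIs and p-values."""
    se = fit.se()
    z = stats.norm.ppf(0.975)
    rows = []
    for outcome in fit.outcome_labels:
        for term in fit.term_names:
            if term == "intercept":
                continue
            if terms is not None and not any(term == t or term.startswith(t + "_") for t in terms):
                continue
            beta = fit.coefficients.loc[outcome, term]
            s = se.loc[outcome, term]
            zval = beta / s if s > 0 else np.inf
            rows.append(
                {
                    "term": term,
                    "outcome": outcome,
                    "or_": float(np.exp(beta)),
                    "ci_low": float(np.exp(beta - z * s)),
                    "ci_high": float(np.exp(beta + z * s)),
                    "p": float(2 * stats.norm.sf(abs(zval))),
                }
            )
    return pd.DataFrame(rows)


def wald_term_test(fit: MultinomFit, outcome: str, term: str) -> float:
    """Two-sided Wald p-value for one coefficient."""
    idx = fit.flat_index(outcome, term)
    beta = fit.coefficients.loc[outcome, term]
    s = np.sqrt(fit.covariance[idx, idx])
    if s <= 0:
        return np.nan
    return float(2 * stats.norm.sf(abs(beta / s)))


def trend_test(fit: MultinomFit, term: str = "alcohol_level_ordinal") -> dict[str, float]:
    """Wald trend p-value per outcome contrast for an ordinal-coded exposure.

    The exposure must enter the fitted model as a single ordinal numeric
    term (0..L-1 level scores).
    """
    if term not in fit.term_names:
        raise UsageError(
            f"trend term {term!r} not in the fitted model; fit with the ordinal coding first"
        )
    return {outcome: wald_term_test(fit, outcome, term) for outcome in fit.outcome_labels}


def with_product(design: pd.DataFrame, term_a: str, term_b: str) -> tuple[pd.DataFrame, list[str]]:
    """Add product (interaction) columns for two terms; returns (design, new column names).

    Each term is dummy-encoded without intercept (first level dropped) before
    multiplying, so categorical x continuous and categorical x categorical
    interactions all reduce to products of encoded columns.
    """
    xa, names_a = encode_terms(design, [term_a], add_intercept=False)
    xb, names_b = encode_terms(design, [term_b], add_intercept=False)
    out = design.copy()
    product_names = []
    for i, na in enumerate(names_a):
        for j, nb in enumerate(names_b):
            name = f"{na}:{nb}"
            out[name] = xa[:, i] * xb[:, j]
            product_names.append(name)
    return out, product_names


def interaction_wald(
    fit: MultinomFit, product_terms: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-product-term Wald p-values, plus a joint chi-square test per contrast.

    ``product_terms`` are design column names created by :func:`with_product`
    (or equivalent) that must be present in the fitted model.
    """
    product_terms = list(product_terms)
    if not product_terms:
        raise UsageError("no product terms supplied")
    missing = [t for t in product_terms if t not in fit.term_names]
    if missing:
        raise UsageError(f"model was fitted without product term(s): {missing}")
    rows = []
    joint = {}
    for outcome in fit.outcome_labels:
        idxs = [fit.flat_index(outcome, t) for t in product_terms]
        betas = np.array([fit.coefficients.loc[outcome, t] for t in product_terms])
        for t, idx, beta in zip(product_terms, idxs, betas):
            s = np.sqrt(fit.covariance[idx, idx])
            rows.append(
                {
                    "outcome": outcome,
                    "term": t,
                    "estimate": float(beta),
                    "p": float(2 * stats.norm.sf(abs(beta / s))) if s > 0 else np.nan,
                }
            )
        sub_cov = fit.covariance[np.ix_(idxs, idxs)]
        stat = float(betas @ np.linalg.solve(sub_cov, betas))
        joint[outcome] = float(stats.chi2.sf(stat, df=len(idxs)))
    return pd.DataFrame(rows), joint


def association_table(
    cohort: pd.DataFrame,
    coding: str,
    covariates: Sequence[str],
    outcome_col: str = "diagnostic_group",
    reference: str = "control",
) -> pd.DataFrame:
    """OR table for one exposure coding, adjusted for the covariate set.

    The cohort must already carry the derived exposure columns (see
    ``exposure.classify_exposure_frame``).
    """
    if coding not in CODING_TERMS:
        raise UsageError(f"unknown coding {coding!r}; choose from {sorted(CODING_TERMS)}")
    terms = CODING_TERMS[coding] + list(covariates)
    fit = fit_multinomial(cohort, cohort[outcome_col], terms, reference=reference)
    table = odds_ratio_table(fit, terms=CODING_TERMS[coding])
    table.insert(0, "coding", coding)
    table["n"] = fit.n
    table["converged"] = fit.converged
    return table
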