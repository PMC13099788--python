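"""Synthetic screening-cohort and microbiome generator.

Emulates the data structure the downstream stages assume: a metadata table
with covariates and zero-inflated right-skewed alcohol intake (two-part
Bernoulli x lognormal mixture with a sex-specific location shift), a
compositional species matrix (per-sample richness ~ truncated normal,
log-normal abundances, a designated set of taxa whose log-mean shifts with
log2 alcohol, columns renormalized to sum to 100), and a binary
advanced-lesion outcome generated from a logistic model with a direct
alcohol path and a mediator path. The outcome generator also returns the
analytically (numerically integrated) true ACME/ADE/proportion mediated at
the configured contrast so recovery tests have ground truth.

Determinism: every operation derives its generator stream from
``(config.seed, stage)`` so the same config yields bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import AlignmentError, ConfigError, SchemaError

_GH_X, _GH_W = np.polynomial.hermite.hermgauss(31)


@dataclass(frozen=True)
class SynthConfig:
    n_participants: int
    n_species: int = 787
    mean_richness: int = 88
    sd_richness: float = 15.5
    prop_nonconsumers: float = 0.13
    median_intake_g: float = 9.0
    sigma_log_intake: float = 1.0
    sex_median_ratio: float = 1.6  # men consume sex_median_ratio^2 x women's median
    n_assoc_taxa_pos: int = 10
    n_assoc_taxa_neg: int = 10
    beta_direct: float = 0.13  # log-odds of advanced lesion per log2-unit alcohol
    beta_taxa: float = 0.3  # per-taxon log-abundance shift per log2-unit alcohol
    gamma_score: float = 0.15  # log-odds per score unit
    mediator_slope: float = 0.12  # used by gaussian_mediator
    mediator_sd: float = 0.5
    mediator_sex_shift: float = 0.05
    baseline_prev_advanced: float = 0.28
    p_adenoma_given_nonadvanced: float = 0.48
    outcome_age_coef: float = 0.1  # per decade of age
    outcome_sex_coef: float = 0.2  # mild sex confounding by default
    seed: int = 0

    def __post_init__(self):
        for name in ("n_participants", "n_species", "mean_richness"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be a positive count, got {getattr(self, name)}")
        for name in ("sd_richness", "median_intake_g", "sigma_log_intake", "mediator_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("prop_nonconsumers", "baseline_prev_advanced", "p_adenoma_given_nonadvanced"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_assoc_taxa_pos", "n_assoc_taxa_neg"):
            if int(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.n_assoc_taxa_pos + self.n_assoc_taxa_neg > self.n_species:
            raise ConfigError(
                "n_assoc_taxa_pos + n_assoc_taxa_neg exceeds n_species"
            )
        if self.sex_median_ratio <= 0:
            raise ConfigError(f"sex_median_ratio must be positive, got {self.sex_median_ratio}")

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        valid = {f.name for f in dc_fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class MediatorModel:
    """True linear-Gaussian mediator law: score = intercept + slope*log2_alcohol + sex_shift*male + N(0, sigma^2)."""

    intercept: float
    slope: float
    sex_shift: float
    sigma: float


@dataclass(frozen=True)
class SynthAbundances:
    matrix: pd.DataFrame  # samples x species, each row sums to 100
    taxa_pos: tuple[str, ...]
    taxa_neg: tuple[str, ...]


@dataclass(frozen=True)
class OutcomeTruth:
    """Numerically integrated true effects at the (observed, observed + 1) log2 contrast."""

    acme: float
    ade: float
    total_effect: float
    prop_mediated: float
    pm_defined: bool
    alpha: float  # calibrated outcome-model intercept


def _rng(config: SynthConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def generate_cohort(config: SynthConfig) -> pd.DataFrame:
    """Participant metadata with covariates and per-beverage alcohol intakes."""
    rng = _rng(config, 1)
    n = config.n_participants
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    male = sex == "male"
    age = rng.integers(55, 78, size=n)
    centre = rng.choice(["centre_1", "centre_2"], size=n)
    affiliation = rng.choice(
        ["norwegian", "non_norwegian", np.nan], size=n, p=[0.92, 0.05, 0.03]
    )
    education = rng.choice(
        ["primary", "high_school", "college_university", np.nan],
        size=n,
        p=[0.25, 0.38, 0.33, 0.04],
    )
    family_history = rng.choice(["no", "yes", "unknown"], size=n, p=[0.8, 0.12, 0.08])
    smoking_status = rng.choice(["never", "former", "current"], size=n, p=[0.45, 0.35, 0.2])
    smoking_quit_years = np.where(
        smoking_status == "former", rng.uniform(0, 30, size=n).round(1), np.nan
    )
    snus_status = rng.choice(["never", "former", "current"], size=n, p=[0.8, 0.1, 0.1])
    snus_quit_years = np.where(
        snus_status == "former", rng.uniform(0, 30, size=n).round(1), np.nan
    )
    height_cm = np.where(
        male, rng.normal(179, 6.5, n), rng.normal(166, 6.0, n)
    ).round(1)
    weight_kg = np.where(
        male, rng.normal(85, 12, n), rng.normal(70, 11, n)
    ).clip(40, 160).round(1)
    moderate = rng.gamma(2.0, 90.0, n).round()
    vigorous = rng.gamma(1.2, 50.0, n).round()
    miss = rng.random(n) < 0.05
    moderate[miss] = np.nan
    vigorous[rng.random(n) < 0.05] = np.nan
    energy = np.exp(rng.normal(np.where(male, np.log(2150.0), np.log(1850.0)), 0.22, n))
    energy = energy.round(0)

    consumer = rng.random(n) >= config.prop_nonconsumers
    mu = np.log(config.median_intake_g) + np.where(
        male, np.log(config.sex_median_ratio), -np.log(config.sex_median_ratio)
    )
    intake = np.exp(rng.normal(mu, config.sigma_log_intake))
    alcohol = np.where(consumer, intake, 0.0).round(2)

    # per-beverage split: sex-typical preference weights (beer-heavy men, wine-heavy women)
    pref = np.where(male[:, None], [6.0, 2.5, 1.0, 0.5], [2.0, 6.0, 1.0, 0.7])
    shares = rng.dirichlet(np.ones(4), size=n) * pref
    shares = shares / shares.sum(axis=1, keepdims=True)
    beverages = alcohol[:, None] * shares
    non_alcoholic = np.where(rng.random(n) < 0.25, rng.gamma(1.5, 40.0, n), 0.0).round(1)

    return pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "centre": centre,
            "affiliation": affiliation,
            "education": education,
            "family_history": family_history,
            "smoking_status": smoking_status,
            "smoking_quit_years": smoking_quit_years,
            "snus_status": snus_status,
            "snus_quit_years": snus_quit_years,
            "height_cm": height_cm,
            "weight_kg": weight_kg,
            "moderate_min_week": moderate,
            "vigorous_min_week": vigorous,
            "energy_kcal_day": energy,
            "alcohol_g_day": alcohol,
            "beer_g_day": beverages[:, 0].round(2),
            "wine_g_day": beverages[:, 1].round(2),
            "spirits_g_day": beverages[:, 2].round(2),
            "drinks_g_day": beverages[:, 3].round(2),
            "non_alcoholic_g_day": non_alcoholic,
        }
    )


def generate_abundances(cohort: pd.DataFrame, config: SynthConfig) -> SynthAbundances:
    """Compositional species matrix with alcohol-shifted designated taxa.

    Realized per-sample richness follows Normal(mean_richness, sd_richness)
    truncated to [1, n_species]; the designated taxa are given the highest
    base prevalence so they are observed in essentially every sample; rows
    are renormalized to sum to 100.
    """
    if "alcohol_g_day" not in cohort.columns:
        raise SchemaError("generate_abundances: cohort lacks an 'alcohol_g_day' column")
    rng = _rng(config, 2)
    n = len(cohort)
    s = config.n_species
    species = np.array([f"s__Species_{j + 1:04d}" for j in range(s)])
    n_pos, n_neg = config.n_assoc_taxa_pos, config.n_assoc_taxa_neg
    taxa_pos = tuple(species[:n_pos])
    taxa_neg = tuple(species[n_pos : n_pos + n_neg])

    t = np.log2(cohort["alcohol_g_day"].to_numpy(dtype=float) + 1.0)
    # base prevalence weights: designated taxa top-ranked, remainder geometric decay
    logw = -6.0 * np.arange(s) / s
    logw[: n_pos + n_neg] = 4.0  # designated taxa near-ubiquitous
    richness = np.rint(rng.normal(config.mean_richness, config.sd_richness, n)).astype(int)
    richness = np.clip(richness, 1, s)
    # weighted sampling without replacement via Gumbel top-k keys
    keys = logw[None, :] + rng.gumbel(size=(n, s))
    order = np.argsort(-keys, axis=1)
    present = np.zeros((n, s), dtype=bool)
    rows = np.repeat(np.arange(n), richness)
    cols = np.concatenate([order[i, : richness[i]] for i in range(n)])
    present[rows, cols] = True

    base_mu = rng.normal(0.0, 1.5, s)
    shift = np.zeros((n, s))
    if n_pos:
        shift[:, :n_pos] = config.beta_taxa * t[:, None]
    if n_neg:
        shift[:, n_pos : n_pos + n_neg] = -config.beta_taxa * t[:, None]
    log_abund = base_mu[None, :] + shift + rng.normal(0.0, 1.0, (n, s))
    abund = np.where(present, np.exp(log_abund), 0.0)
    abund = abund / abund.sum(axis=1, keepdims=True) * 100.0
    matrix = pd.DataFrame(abund, index=cohort["participant_id"].to_numpy(), columns=species)
    matrix.index.name = "participant_id"
    return SynthAbundances(matrix=matrix, taxa_pos=taxa_pos, taxa_neg=taxa_neg)


def gaussian_mediator(
    cohort: pd.DataFrame, config: SynthConfig
) -> tuple[np.ndarray, MediatorModel]:
    """Draw a mediator with an exactly known linear-Gaussian law.

    Used by parameter-recovery tests that need the mediator distribution in
    closed form rather than via the abundance pipeline.
    """
    rng = _rng(config, 4)
    t = np.log2(cohort["alcohol_g_day"].to_numpy(dtype=float) + 1.0)
    male = (cohort["sex"].astype(str) == "male").to_numpy(dtype=float)
    model = MediatorModel(
        intercept=0.0,
        slope=config.mediator_slope,
        sex_shift=config.mediator_sex_shift,
        sigma=config.mediator_sd,
    )
    score = (
        model.intercept
        + model.slope * t
        + model.sex_shift * male
        + rng.normal(0.0, model.sigma, len(cohort))
    )
    return score, model


def _true_potential_probs(
    alpha: float,
    config: SynthConfig,
    t: np.ndarray,
    cov_lp: np.ndarray,
    med: MediatorModel,
    med_cov: np.ndarray,
    delta: float = 1.0,
) -> dict[tuple[int, int], np.ndarray]:
    gamma = config.gamma_score
    mu0 = med.intercept + med.slope * t + med_cov
    mu1 = mu0 + med.slope * delta
    eta0 = alpha + config.beta_direct * t + cov_lp
    eta1 = eta0 + config.beta_direct * delta
    out = {}
    for ai, eta in ((0, eta0), (1, eta1)):
        for mi, mu in ((0, mu0), (1, mu1)):
            vals = expit(eta[:, None] + gamma * (mu[:, None] + np.sqrt(2) * med.sigma * _GH_X))
            out[(ai, mi)] = vals @ _GH_W / np.sqrt(np.pi)
    return out


def generate_outcome(
    cohort: pd.DataFrame,
    score: Sequence[float],
    config: SynthConfig,
    mediator_model: Optional[MediatorModel] = None,
    delta: float = 1.0,
) -> tuple[pd.DataFrame, OutcomeTruth]:
    """Draw the lesion outcome and return it with the generator's true effects.

    logit P(advanced) = alpha + beta_direct*log2(alcohol+1) + gamma_score*score
    + covariate terms, with alpha calibrated by root-finding so the mean
    probability equals ``baseline_prev_advanced``. The true ACME/ADE/total
    at the (observed, observed + delta) contrast are computed by integrating
    the potential-outcome definitions over the simulated covariate
    distribution with Gauss-Hermite quadrature, using the mediator law
    (supplied, or estimated by OLS from the provided score when absent).
    """
    score = np.asarray(score, dtype=float)
    if score.shape[0] != len(cohort):
        raise AlignmentError(
            f"score length {score.shape[0]} does not match cohort length {len(cohort)}"
        )
    rng = _rng(config, 3)
    t = np.log2(cohort["alcohol_g_day"].to_numpy(dtype=float) + 1.0)
    male = (cohort["sex"].astype(str) == "male").to_numpy(dtype=float)
    age = cohort["age"].to_numpy(dtype=float)
    cov_lp = config.outcome_age_coef * (age - 66.0) / 10.0 + config.outcome_sex_coef * male
    lp_partial = config.beta_direct * t + config.gamma_score * score + cov_lp

    def mean_prev(alpha):
        return float(np.mean(expit(alpha + lp_partial))) - config.baseline_prev_advanced

    alpha = brentq(mean_prev, -30.0, 30.0)
    p_adv = expit(alpha + lp_partial)
    advanced = (rng.random(len(cohort)) < p_adv).astype(int)
    adenoma = rng.random(len(cohort)) < config.p_adenoma_given_nonadvanced
    group = np.where(
        advanced == 1,
        "advanced_lesion",
        np.where(adenoma, "non_advanced_adenoma", "control"),
    )
    out = cohort.copy()
    out["advanced"] = advanced
    out["diagnostic_group"] = group

    if mediator_model is None:
        X = np.column_stack([np.ones_like(t), t, male])
        beta, _, _, _ = np.linalg.lstsq(X, score, rcond=None)
        resid = score - X @ beta
        sigma = float(np.sqrt(resid @ resid / max(len(t) - 3, 1)))
        mediator_model = MediatorModel(
            intercept=float(beta[0]), slope=float(beta[1]), sex_shift=float(beta[2]), sigma=sigma
        )
    med_cov = mediator_model.sex_shift * male
    probs = _true_potential_probs(alpha, config, t, cov_lp, mediator_model, med_cov, delta)
    acme = 0.5 * float(
        np.mean(probs[(1, 1)] - probs[(1, 0)]) + np.mean(probs[(0, 1)] - probs[(0, 0)])
    )
    ade = 0.5 * float(
        np.mean(probs[(1, 0)] - probs[(0, 0)]) + np.mean(probs[(1, 1)] - probs[(0, 1)])
    )
    total = float(np.mean(probs[(1, 1)] - probs[(0, 0)]))
    pm_defined = abs(total) > 1e-12
    truth = OutcomeTruth(
        acme=acme,
        ade=ade,
        total_effect=total,
        prop_mediated=acme / total if pm_defined else np.nan,
        pm_defined=pm_defined,
        alpha=alpha,
    )
    return out, truth
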