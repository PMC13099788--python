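"""Alcohol-exposure derivation, covariate coding and diagnostic grouping.

All classification boundaries are right-open at 10 and 20 g/day:
level ``zero`` (0), ``gt0_lt10`` (>0, <10), ``ge10_lt20`` ([10, 20)),
``ge20`` ([20, inf)). Guideline adherence uses sex-specific thresholds
(10 g/day for women, 20 g/day for men): ``full`` at exactly 0 g/day,
``partial`` below the threshold, ``non`` at or above it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError

#: kcal per gram of ethanol (standard nutrition constant).
ETHANOL_KCAL_PER_G = 7.0
#: grams of pure ethanol per standard alcohol unit (Norwegian convention).
GRAMS_PER_UNIT = 12.0

#: standardized serving volumes (mL) used for per-beverage bookkeeping
BEVERAGE_UNIT_ML = {
    "wine": 150,
    "beer": 330,
    "spirits": 40,
    "drinks": 200,
    "non_alcoholic": 330,
}

LEVELS = ("zero", "gt0_lt10", "ge10_lt20", "ge20")
ADHERENCE = ("full", "partial", "non")
GROUPS = ("control", "non_advanced_adenoma", "advanced_lesion")
ADVANCED_SUBTYPES = ("crc", "advanced_adenoma", "advanced_serrated")

#: sex-specific guideline thresholds in g/day
ADHERENCE_THRESHOLD = {"female": 10.0, "male": 20.0}

#: sex-specific plausibility limits on reported energy intake (kcal/day)
ENERGY_LIMITS = {"female": (600.0, 3500.0), "male": (800.0, 4200.0)}

#: years since quitting below which a former user still counts as a user
QUIT_WINDOW_YEARS = 10.0


@dataclass(frozen=True)
class AlcoholExposure:
    """Derived alcohol-exposure variables for one participant."""

    ethanol_g_day: float
    units_day: float
    level: str
    adherence: str
    consumer: bool
    ethanol_e_pct: Optional[float] = None

    def __post_init__(self):
        if self.level not in LEVELS:
            raise DomainError(f"unknown level {self.level!r}")
        if self.adherence not in ADHERENCE:
            raise DomainError(f"unknown adherence {self.adherence!r}")


@dataclass(frozen=True)
class DiagnosticGroup:
    """Colonoscopy diagnosis collapsed to the three analysis groups."""

    group: str
    advanced_subtype: Optional[str] = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise DomainError(f"unknown group {self.group!r}")
        if self.advanced_subtype is not None:
            if self.group != "advanced_lesion":
                raise DomainError("advanced_subtype only valid for advanced_lesion")
            if self.advanced_subtype not in ADVANCED_SUBTYPES:
                raise DomainError(f"unknown subtype {self.advanced_subtype!r}")


def ethanol_energy_pct(ethanol_g_day: float, energy_kcal_day: float) -> float:
    """Percent of total energy intake contributed by ethanol (7 kcal/g)."""
    if energy_kcal_day <= 0:
        raise DomainError(f"energy_kcal_day must be positive, got {energy_kcal_day}")
    if ethanol_g_day < 0:
        raise DomainError(f"ethanol_g_day must be non-negative, got {ethanol_g_day}")
    return 100.0 * ethanol_g_day * ETHANOL_KCAL_PER_G / energy_kcal_day


def intake_level(ethanol_g_day: float) -> str:
    """Consumption-level category for a g/day intake."""
    if ethanol_g_day < 0 or not np.isfinite(ethanol_g_day):
        raise DomainError(f"ethanol_g_day must be finite and non-negative, got {ethanol_g_day}")
    if ethanol_g_day == 0:
        return "zero"
    if ethanol_g_day < 10:
        return "gt0_lt10"
    if ethanol_g_day < 20:
        return "ge10_lt20"
    return "ge20"


def classify_exposure(
    ethanol_g_day: float, sex: str, energy_kcal_day: Optional[float] = None
) -> AlcoholExposure:
    """Derive level, guideline adherence, units/day (and E% when energy given)."""
    sex = _check_sex(sex)
    level = intake_level(ethanol_g_day)
    threshold = ADHERENCE_THRESHOLD[sex]
    if ethanol_g_day == 0:
        adherence = "full"
    elif ethanol_g_day < threshold:
        adherence = "partial"
    else:
        adherence = "non"
    e_pct = None
    if energy_kcal_day is not None:
        e_pct = ethanol_energy_pct(ethanol_g_day, energy_kcal_day)
    return AlcoholExposure(
        ethanol_g_day=float(ethanol_g_day),
        units_day=float(ethanol_g_day) / GRAMS_PER_UNIT,
        level=level,
        adherence=adherence,
        consumer=ethanol_g_day > 0,
        ethanol_e_pct=e_pct,
    )


def _check_sex(sex: str) -> str:
    s = str(sex).lower()
    if s not in ("female", "male"):
        raise DomainError(f"sex must be 'female' or 'male', got {sex!r}")
    return s


def _require_columns(df: pd.DataFrame, cols, op: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{op}: missing required column(s) {missing}")


def apply_energy_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop rows whose reported energy intake is outside sex-specific limits.

    Returns the retained table and a log with counts per exclusion reason.
    """
    _require_columns(cohort, ["energy_kcal_day", "sex"], "apply_energy_exclusions")
    log = {"low_energy": 0, "high_energy": 0, "n_in": int(len(cohort)), "n_out": 0}
    if cohort.empty:
        return cohort.copy(), log
    sex = cohort["sex"].astype(str).str.lower()
    if not sex.isin(["female", "male"]).all():
        bad = sorted(set(sex[~sex.isin(["female", "male"])]))
        raise SchemaError(f"apply_energy_exclusions: unrecognized sex value(s) {bad}")
    energy = cohort["energy_kcal_day"].astype(float)
    low = sex.map({k: v[0] for k, v in ENERGY_LIMITS.items()})
    high = sex.map({k: v[1] for k, v in ENERGY_LIMITS.items()})
    is_low = energy < low
    is_high = energy > high
    keep = ~(is_low | is_high)
    log["low_energy"] = int(is_low.sum())
    log["high_energy"] = int(is_high.sum())
    log["n_out"] = int(keep.sum())
    return cohort.loc[keep].copy(), log


def _user_within_window(status: pd.Series, quit_years: pd.Series) -> pd.Series:
    """Current/occasional users, or former users who quit < 10 years ago."""
    status = status.astype(str).str.lower()
    current = status.isin(["current", "regular", "occasional"])
    former = status == "former"
    recent_quit = former & (quit_years.astype(float) < QUIT_WINDOW_YEARS)
    return current | recent_quit


def classify_exposure_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorized exposure derivation: adds level/adherence/units/consumer columns.

    Also adds ``log2_alcohol`` = log2(g/day + 1), the continuous per-twofold
    coding, and ``ethanol_e_pct`` when an energy column is present.
    """
    _require_columns(cohort, ["alcohol_g_day", "sex"], "classify_exposure_frame")
    out = cohort.copy()
    g = out["alcohol_g_day"].astype(float)
    if (g < 0).any() or not np.isfinite(g).all():
        raise DomainError("alcohol_g_day must be finite and non-negative")
    sex = out["sex"].astype(str).str.lower()
    level = np.select([g == 0, g < 10, g < 20], LEVELS[:3], default="ge20")
    threshold = sex.map(ADHERENCE_THRESHOLD)
    adherence = np.select([g == 0, g < threshold], ["full", "partial"], default="non")
    out["alcohol_level"] = pd.Categorical(level, categories=list(LEVELS), ordered=True)
    out["adherence"] = pd.Categorical(adherence, categories=list(ADHERENCE), ordered=True)
    out["units_day"] = g / GRAMS_PER_UNIT
    out["consumer"] = g > 0
    out["log2_alcohol"] = np.log2(g + 1.0)
    out["alcohol_per10g"] = g / 10.0
    out["alcohol_level_ordinal"] = out["alcohol_level"].cat.codes.astype(int)
    if "energy_kcal_day" in out.columns:
        energy = out["energy_kcal_day"].astype(float)
        if (energy <= 0).any():
            raise DomainError("energy_kcal_day must be positive for E% derivation")
        out["ethanol_e_pct"] = 100.0 * g * ETHANOL_KCAL_PER_G / energy
    return out


def derive_covariates(raw: pd.DataFrame) -> pd.DataFrame:
    """Derive analysis covariates from raw questionnaire fields.

    Adds:

    - ``mod_vig_min_week`` = moderate + 2 x vigorous activity minutes/week
      (missing set to cohort median afterwards),
    - ``smoker`` / ``snuser`` booleans: regular or occasional users, or former
      users who quit within the last ten years,
    - ``bmi`` from self-reported weight (kg) and height (cm), missing set to
      cohort median,
    - "missing" category levels for education, affiliation, family history and
      smoking status codings.

    Missingness is encoded, never fatal.
    """
    out = raw.copy()
    if "moderate_min_week" in out.columns and "vigorous_min_week" in out.columns:
        mod = pd.to_numeric(out["moderate_min_week"], errors="coerce")
        vig = pd.to_numeric(out["vigorous_min_week"], errors="coerce")
        activity = mod + 2.0 * vig
        out["mod_vig_min_week"] = activity.fillna(activity.median())
    if "smoking_status" in out.columns:
        quit_years = pd.to_numeric(
            out.get("smoking_quit_years", pd.Series(np.nan, index=out.index)),
            errors="coerce",
        ).fillna(np.inf)
        out["smoker"] = _user_within_window(out["smoking_status"], quit_years)
    if "snus_status" in out.columns:
        quit_years = pd.to_numeric(
            out.get("snus_quit_years", pd.Series(np.nan, index=out.index)),
            errors="coerce",
        ).fillna(np.inf)
        out["snuser"] = _user_within_window(out["snus_status"], quit_years)
    if "weight_kg" in out.columns and "height_cm" in out.columns:
        weight = pd.to_numeric(out["weight_kg"], errors="coerce")
        height_m = pd.to_numeric(out["height_cm"], errors="coerce") / 100.0
        bmi = weight / height_m**2
        out["bmi"] = bmi.fillna(bmi.median())
    elif "bmi" in out.columns:
        bmi = pd.to_numeric(out["bmi"], errors="coerce")
        out["bmi"] = bmi.fillna(bmi.median())
    for col in ("education", "affiliation", "family_history", "smoking_status"):
        if col in out.columns:
            coded = out[col].astype(object)
            coded[pd.isna(coded)] = "missing"
            out[col + "_coded"] = coded.astype(str)
    return out


def binary_advanced(group: pd.Series) -> pd.Series:
    """Advanced-lesion indicator; non-advanced adenomas grouped with controls."""
    g = group.astype(str)
    known = set(GROUPS)
    bad = sorted(set(g) - known)
    if bad:
        raise SchemaError(f"binary_advanced: unknown diagnostic group value(s) {bad}")
    return (g == "advanced_lesion").astype(int)
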