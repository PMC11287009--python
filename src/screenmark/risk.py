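"""10-year ASCVD risk equations, recalibration and category cut-offs.

The risk equation is the usual survival-type score: with linear predictor
``lp = beta . x`` and its value ``lp_bar`` at the reference covariate means,
the 10-year risk is ``1 - S0 ** exp(lp - lp_bar)`` where ``S0`` is the
sex-specific 10-year baseline survival.  Coefficients, reference means and
``S0`` are configuration — published model coefficients can be dropped in,
and the test suite uses a documented synthetic set.

Recalibration to a target population replaces ``S0`` by the unique value
making the cohort's mean predicted risk equal an observed 10-year risk
(one-dimensional monotone root-find); slopes are untouched.

Category cut-offs are half-open on the right: a risk exactly at a
threshold belongs to the higher category, so with cut-offs 5% and 10% a
risk of 5.0% is intermediate and 10.0% is high.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "SexEquation",
    "RiskEquation",
    "RiskCutoffs",
    "ten_year_risk",
    "risk_table",
    "recalibrate",
    "categorize",
    "categorize_table",
    "HARD_THREE_CATEGORY",
    "HARD_FOUR_CATEGORY_SCHEMES",
    "SOFT_THREE_CATEGORY",
    "SOFT_FOUR_CATEGORY_SCHEMES",
]


@dataclass(frozen=True)
class SexEquation:
    """One sex's coefficients (log hazard ratios), reference means and
    10-year baseline survival."""

    predictors: tuple[str, ...]
    coefficients: tuple[float, ...]
    reference_means: tuple[float, ...]
    baseline_survival: float

    def __post_init__(self) -> None:
        k = len(self.predictors)
        if len(self.coefficients) != k or len(self.reference_means) != k:
            raise ValueError("coefficients and reference means must match predictors")
        if not (0.0 < self.baseline_survival < 1.0):
            raise ValueError("baseline survival must lie in (0, 1)")

    def linear_predictor(self, profile: Mapping[str, float]) -> float:
        lp = 0.0
        for name, beta in zip(self.predictors, self.coefficients):
            if name not in profile or pd.isna(profile[name]):
                raise ValueError(f"missing predictor {name!r}")
            lp += beta * float(profile[name])
        return lp

    @property
    def reference_lp(self) -> float:
        return float(np.dot(self.coefficients, self.reference_means))


@dataclass(frozen=True)
class RiskEquation:
    """Sex-specific pair of equations, keyed 'female' / 'male'."""

    female: SexEquation
    male: SexEquation

    def for_sex(self, sex) -> SexEquation:
        if sex in ("male", 1, True):
            return self.male
        if sex in ("female", 0, False):
            return self.female
        raise ValueError(f"unrecognised sex value {sex!r}")


def ten_year_risk(profile: Mapping[str, float], eq: RiskEquation) -> float:
    """Predicted 10-year ASCVD risk for one covariate profile, in (0, 1)."""
    if "sex" not in profile:
        raise ValueError("missing predictor 'sex'")
    sx = eq.for_sex(profile["sex"])
    rel = np.exp(sx.linear_predictor(profile) - sx.reference_lp)
    return float(1.0 - sx.baseline_survival**rel)


def risk_table(cohort: pd.DataFrame, eq: RiskEquation) -> np.ndarray:
    """Vectorised 10-year risks for a covariate table with a 'sex' column."""
    if "sex" not in cohort.columns:
        raise ValueError("missing predictor 'sex'")
    risks = np.empty(len(cohort))
    sex = cohort["sex"].to_numpy()
    male = np.array([s in ("male", 1, True) for s in sex])
    for is_male, sx in ((True, eq.male), (False, eq.female)):
        mask = male if is_male else ~male
        if not mask.any():
            continue
        lp = np.zeros(mask.sum())
        for name, beta in zip(sx.predictors, sx.coefficients):
            if name not in cohort.columns:
                raise ValueError(f"missing predictor {name!r}")
            col = cohort.loc[mask, name].to_numpy(dtype=float)
            if np.isnan(col).any():
                raise ValueError(f"missing predictor {name!r} (NaN values)")
            lp += beta * col
        risks[mask] = 1.0 - sx.baseline_survival ** np.exp(lp - sx.reference_lp)
    return risks


def recalibrate(
    eq: RiskEquation,
    cohort: pd.DataFrame,
    observed_10y_risk: "float | Mapping[str, float]",
    tol: float = 1e-10,
) -> RiskEquation:
    """Replace each sex's baseline survival so that the cohort's mean
    predicted risk equals the observed 10-year risk.

    ``observed_10y_risk`` is either a single fraction applied to both sexes
    (each sex matched within its own stratum) or a mapping per sex.  The
    mean risk is strictly decreasing in ``S0``, so the root is unique.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if not isinstance(observed_10y_risk, Mapping):
        observed_10y_risk = {"female": observed_10y_risk, "male": observed_10y_risk}

    out = {}
    sexcol = cohort["sex"].to_numpy()
    male = np.array([s in ("male", 1, True) for s in sexcol])
    for key, sx, mask in (("female", eq.female, ~male), ("male", eq.male, male)):
        target = float(observed_10y_risk[key])
        if not (0.0 < target < 1.0):
            raise ValueError("observed risk must lie in (0, 1)")
        if not mask.any():
            out[key] = sx
            continue
        lp = np.zeros(mask.sum())
        for name, beta in zip(sx.predictors, sx.coefficients):
            lp += beta * cohort.loc[mask, name].to_numpy(dtype=float)
        rel = np.exp(lp - sx.reference_lp)

        def gap(s0):
            return float(np.mean(1.0 - s0**rel)) - target

        lo, hi = 1e-12, 1.0 - 1e-12
        if gap(lo) < 0 or gap(hi) > 0:
            raise ValueError("no baseline survival in (0, 1) matches the target")
        s0 = brentq(gap, lo, hi, xtol=tol)
        out[key] = replace(sx, baseline_survival=float(s0))
    return RiskEquation(female=out["female"], male=out["male"])


@dataclass(frozen=True)
class RiskCutoffs:
    """Ordered thresholds (risk fractions) and the category labels of the
    half-open intervals they delimit (closed on the left)."""

    thresholds: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        th = np.asarray(self.thresholds, dtype=float)
        if np.any(th <= 0) or np.any(th >= 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if np.any(np.diff(th) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if len(self.labels) != len(th) + 1:
            raise ValueError("need one more label than thresholds")

    @property
    def non_high_labels(self) -> tuple[str, ...]:
        return self.labels[:-1]


def categorize(risk: float, cutoffs: RiskCutoffs) -> str:
    """Label of the half-open interval containing ``risk`` (in [0, 1))."""
    if not (0.0 <= risk < 1.0):
        raise ValueError(f"risk {risk} outside [0, 1)")
    k = int(np.searchsorted(cutoffs.thresholds, risk, side="right"))
    return cutoffs.labels[k]


def categorize_table(risks: np.ndarray, cutoffs: RiskCutoffs) -> np.ndarray:
    risks = np.asarray(risks, dtype=float)
    if np.any((risks < 0) | (risks >= 1)):
        raise ValueError("risks outside [0, 1)")
    ks = np.searchsorted(cutoffs.thresholds, risks, side="right")
    return np.asarray(cutoffs.labels, dtype=object)[ks]


# Guideline cut-off schemes.  Hard-outcome model: high risk at >= 10%;
# soft-outcome model: high risk at >= 20%.
HARD_THREE_CATEGORY = RiskCutoffs((0.05, 0.10), ("low", "intermediate", "high"))
HARD_FOUR_CATEGORY_SCHEMES = {
    "2.5-5": RiskCutoffs(
        (0.025, 0.05, 0.10), ("low", "intermediate_low", "intermediate_high", "high")
    ),
    "2.5-7.5": RiskCutoffs(
        (0.025, 0.075, 0.10), ("low", "intermediate_low", "intermediate_high", "high")
    ),
    "5-7.5": RiskCutoffs(
        (0.05, 0.075, 0.10), ("low", "intermediate_low", "intermediate_high", "high")
    ),
}
SOFT_THREE_CATEGORY = RiskCutoffs((0.10, 0.20), ("low", "intermediate", "high"))
SOFT_FOUR_CATEGORY_SCHEMES = {
    "5-10": RiskCutoffs(
        (0.05, 0.10, 0.20), ("low", "intermediate_low", "intermediate_high", "high")
    ),
    "5-15": RiskCutoffs(
        (0.05, 0.15, 0.20), ("low", "intermediate_low", "intermediate_high", "high")
    ),
    "10-15": RiskCutoffs(
        (0.10, 0.15, 0.20), ("low", "intermediate_low", "intermediate_high", "high")
    ),
}
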