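"""Named parameter fixtures: the "ckb-like" generator calibration, the
published statin cost-effectiveness parameters, and population counts by
risk category.

The ckb-like generator anchors everything that downstream estimates are
checked against to published point estimates for a large Chinese cohort:

* mean sojourn times — low-risk 10.5 years, intermediate-risk 5.3 years
  (total exit rates 1/10.5 and 1/5.3 per year);
* embedded jump shares into the ASCVD state — 2.2% from low, 4.1% from
  intermediate, 10.4% from high;
* reversal shares — intermediate -> low 7.4%, high -> intermediate 8.8%;
* baseline category mix — roughly 50/20/30% low/intermediate/high.

Shares that are not published (transitions to non-ASCVD death, the split
of the remaining low-state exits, and the high-state total exit rate) are
set to documented values so each row's jump shares sum to one.  In
particular the high state, whose published exits are only 10.4% (ASCVD)
and 8.8% (reversal), sends the remaining 80.8% of its jumps to non-ASCVD
death — a consequence of the high-risk group being dominated by older
individuals.  The high-state mean sojourn is set to 6 years.
"""

from __future__ import annotations

import numpy as np

from .econ import EconParams
from .risk import RiskEquation, SexEquation
from .screening import InitialCohort
from .synthetic import GeneratorSpec

__all__ = [
    "ckb_like_generator",
    "table_econ_params",
    "population_millions",
    "initial_cohort_from_population",
    "example_risk_equation",
]


def _row(exit_rate: float, shares: dict[str, float], labels, self_label: str):
    if abs(sum(shares.values()) - 1.0) > 1e-12:
        raise ValueError(f"jump shares for {self_label} do not sum to 1")
    row = np.zeros(len(labels))
    for lab, s in shares.items():
        row[labels.index(lab)] = exit_rate * s
    row[labels.index(self_label)] = -exit_rate
    return row


def ckb_like_generator(
    scheme: str = "three_category",
    n_subjects: int = 30_000,
    seed: int = 20_240_716,
    visit_schedule=(0.0, 4.0, 9.0),
    resurvey_fraction=(0.66, 0.84),
    horizon: float = 12.8,
) -> GeneratorSpec:
    """The calibrated synthetic data-generating process.

    three_category: states low / intermediate / high / ascvd /
    non_ascvd_death.  four_category splits the intermediate band in two
    (intermediate_low, intermediate_high) with a faster progression in the
    upper band; only the three-category rates carry published anchors.
    """
    if scheme == "three_category":
        labels = ["low", "intermediate", "high", "ascvd", "non_ascvd_death"]
        Q = np.vstack(
            [
                _row(1 / 10.5, {"intermediate": 0.900, "high": 0.040,
                                "ascvd": 0.022, "non_ascvd_death": 0.038},
                     labels, "low"),
                _row(1 / 5.3, {"low": 0.074, "high": 0.840,
                               "ascvd": 0.041, "non_ascvd_death": 0.045},
                     labels, "intermediate"),
                _row(1 / 6.0, {"intermediate": 0.088, "ascvd": 0.104,
                               "non_ascvd_death": 0.808},
                     labels, "high"),
                np.zeros(5),
                np.zeros(5),
            ]
        )
        init = np.array([0.498, 0.205, 0.297, 0.0, 0.0])
    elif scheme == "four_category":
        labels = ["low", "intermediate_low", "intermediate_high", "high",
                  "ascvd", "non_ascvd_death"]
        Q = np.vstack(
            [
                _row(1 / 10.5, {"intermediate_low": 0.840, "intermediate_high": 0.060,
                                "high": 0.040, "ascvd": 0.022,
                                "non_ascvd_death": 0.038}, labels, "low"),
                _row(1 / 5.3, {"low": 0.074, "intermediate_high": 0.600,
                               "high": 0.240, "ascvd": 0.041,
                               "non_ascvd_death": 0.045}, labels, "intermediate_low"),
                _row(1 / 3.5, {"intermediate_low": 0.100, "high": 0.700,
                               "ascvd": 0.080, "non_ascvd_death": 0.120},
                     labels, "intermediate_high"),
                _row(1 / 6.0, {"intermediate_high": 0.088, "ascvd": 0.104,
                               "non_ascvd_death": 0.808}, labels, "high"),
                np.zeros(6),
                np.zeros(6),
            ]
        )
        init = np.array([0.498, 0.120, 0.085, 0.297, 0.0, 0.0])
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return GeneratorSpec(
        state_labels=tuple(labels),
        true_Q=Q,
        initial_distribution=init,
        n_subjects=n_subjects,
        visit_schedule=tuple(visit_schedule),
        resurvey_fraction=resurvey_fraction,
        horizon=horizon,
        seed=seed,
    )


def table_econ_params() -> EconParams:
    """Published statin cost-effectiveness parameters (2019 CN¥):
    per 100,000 treated person-years 225.17 QALYs gained, 251.86 ASCVD
    events prevented, 85.81 diabetes and 34.37 myopathy cases caused;
    incremental statin cost 212.34 per person-year (low limit 70.78);
    health check 30.00."""
    return EconParams()


# National population (millions) by predicted 10-year risk band, hard- and
# soft-outcome risk models.
_POPULATION_HARD = {
    "<2.5%": 273.89,
    "2.5-4.9%": 153.51,
    "5.0-7.4%": 90.16,
    "7.5-9.9%": 61.46,
    ">=10%": 244.05,
}
_POPULATION_SOFT = {
    "<5.0%": 271.66,
    "5.0-9.9%": 172.20,
    "10.0-14.9%": 102.24,
    "15.0-19.9%": 67.28,
    ">=20%": 209.66,
}


def population_millions(model: str = "hard") -> dict[str, float]:
    """ASCVD-free national population (millions) per risk band."""
    if model == "hard":
        return dict(_POPULATION_HARD)
    if model == "soft":
        return dict(_POPULATION_SOFT)
    raise ValueError(f"unknown model {model!r}")


def initial_cohort_from_population(
    scheme: str = "three_category",
    model: str = "hard",
    cutoff_key: str = "5-7.5",
) -> InitialCohort:
    """Initial non-high cohort (millions) by merging the population risk
    bands into a protocol scheme's categories.

    For the hard model the bands are <2.5, 2.5-4.9, 5.0-7.4, 7.5-9.9 (and
    >=10 high); three-category merges the first two into 'low' and the next
    two into 'intermediate'; four-category keys pick the cut-off pair
    ('2.5-5', '2.5-7.5' or '5-7.5').
    """
    pop = population_millions(model)
    bands = list(pop.values())[:4]  # non-high bands in ascending risk order
    if scheme == "three_category":
        counts = {"low": bands[0] + bands[1], "intermediate": bands[2] + bands[3]}
    elif scheme == "four_category":
        merges = {
            "2.5-5": (1, 2),   # low = band0 | int_low = band1 | int_high = 2+3
            "2.5-7.5": (1, 3),
            "5-7.5": (2, 3),
        }
        if cutoff_key not in merges:
            raise ValueError(f"unknown cut-off key {cutoff_key!r}")
        a, b = merges[cutoff_key]
        counts = {
            "low": sum(bands[:a]),
            "intermediate_low": sum(bands[a:b]),
            "intermediate_high": sum(bands[b:]),
        }
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return InitialCohort(counts, unit="millions")


def example_risk_equation() -> RiskEquation:
    """A documented synthetic risk equation for tests and examples.

    Coefficients are plausible log hazard ratios for a non-laboratory
    10-year ASCVD score (not published values): per year of age 0.072, per
    mmHg systolic 0.016, per mmHg diastolic 0.004, blood-pressure
    medication 0.35, daily smoking 0.45, diabetes history 0.60, per cm
    waist 0.010.  Baseline survival 0.965 (women) and 0.945 (men) at the
    reference means of the default covariate model.
    """
    predictors = (
        "age", "systolic_bp", "diastolic_bp", "bp_medication",
        "daily_smoker", "diabetes_history", "waist_circumference",
    )
    coefs = (0.072, 0.016, 0.004, 0.35, 0.45, 0.60, 0.010)
    means_f = (51.0, 127.0, 77.0, 0.11, 0.02, 0.027, 77.5)
    means_m = (51.5, 130.0, 78.0, 0.09, 0.57, 0.026, 81.0)
    return RiskEquation(
        female=SexEquation(predictors, coefs, means_f, 0.965),
        male=SexEquation(predictors, coefs, means_m, 0.945),
    )
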