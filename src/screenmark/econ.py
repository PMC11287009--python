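"""Events prevented, QALYs, treatment harms and costs per protocol.

Earlier identification of high-risk individuals converts unidentified
high-risk person-years into statin-treated person-years.  Benefits and
harms scale linearly with that difference: per 100,000 treated person-years
statin therapy prevents a fixed number of ASCVD events, gains QALYs, and
causes new diabetes and myopathy cases; each treated person-year carries an
incremental drug-plus-services cost, and each screen a health-check cost.
All money is 2019 Chinese Yuan (CN¥).

Sign conventions are explicit: ``delta_person_years`` is reference minus
alternative (positive means the alternative identifies people earlier and
treats them longer, which *adds* statin cost); screening-cost savings must
come from a smaller screening volume.  A protocol is cost-saving when its
total cost delta is <= 0, and the optimal protocol is the one preventing
the most events among the cost-saving set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .screening import EvaluationResult, InitialCohort

__all__ = [
    "EconParams",
    "ProtocolComparison",
    "compare_to_reference",
    "select_optimal",
    "scale_initial_cohort",
    "comparison_table",
]


@dataclass(frozen=True)
class EconParams:
    """Statin-treatment effectiveness/harm rates (per 100,000 treated
    person-years), incremental treatment costs (per person-year) and the
    health-check cost, all in 2019 CN¥ where monetary."""

    qaly_gain_rate: float = 225.17
    events_prevented_rate: float = 251.86
    diabetes_caused_rate: float = 85.81
    myopathy_caused_rate: float = 34.37
    statin_incremental_cost: float = 212.34
    statin_incremental_cost_low: float = 70.78
    cost_per_health_check: float = 30.00
    discount_rate: float = 0.0  # hook; no discounting by default

    def __post_init__(self) -> None:
        for name in (
            "qaly_gain_rate", "events_prevented_rate", "diabetes_caused_rate",
            "myopathy_caused_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "statin_incremental_cost", "statin_incremental_cost_low",
            "cost_per_health_check",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.statin_incremental_cost_low > self.statin_incremental_cost:
            raise ValueError("low-limit statin cost must not exceed the average cost")

    def with_low_statin_cost(self) -> "EconParams":
        return replace(self, statin_incremental_cost=self.statin_incremental_cost_low)


@dataclass(eq=False)
class ProtocolComparison:
    """Deltas of one protocol versus the uniform reference.

    ``delta_person_years`` = reference minus alternative unidentified
    person-years (positive = earlier identification).  ``delta_screens`` =
    alternative minus reference screening volume.  Negative
    ``delta_total_cost`` is a saving.
    """

    protocol_name: str
    scheme: str
    delta_person_years: float
    delta_screens: float
    events_prevented: float
    qalys_gained: float
    diabetes_caused: float
    myopathy_caused: float
    delta_statin_cost: float
    delta_screening_cost: float
    delta_total_cost: float
    total_screens: float
    intervals: dict | None = None
    ci: dict | None = None  # optional percentile intervals per field

    @property
    def cost_saving(self) -> bool:
        return self.delta_total_cost <= 0

    def to_dict(self) -> dict:
        d = {
            "protocol": self.protocol_name,
            "scheme": self.scheme,
            "delta_person_years": self.delta_person_years,
            "delta_screens": self.delta_screens,
            "events_prevented": self.events_prevented,
            "qalys_gained": self.qalys_gained,
            "diabetes_caused": self.diabetes_caused,
            "myopathy_caused": self.myopathy_caused,
            "delta_statin_cost": self.delta_statin_cost,
            "delta_screening_cost": self.delta_screening_cost,
            "delta_total_cost": self.delta_total_cost,
            "total_screens": self.total_screens,
            "cost_saving": self.cost_saving,
        }
        if self.ci:
            for k, (lo, hi) in self.ci.items():
                d[f"{k}_lo"] = lo
                d[f"{k}_hi"] = hi
        return d


def compare_to_reference(
    alt: EvaluationResult,
    ref: EvaluationResult,
    params: EconParams,
) -> ProtocolComparison:
    """Linear conversion of person-year and screening-volume differences
    into events, QALYs, harms and cost deltas versus the reference."""
    if abs(alt.cohort_total - ref.cohort_total) > 1e-9 * max(1.0, ref.cohort_total):
        raise ValueError("alternative and reference were run on different cohorts")
    if alt.horizon != ref.horizon:
        raise ValueError("alternative and reference use different horizons")
    dpy = ref.person_years_unidentified - alt.person_years_unidentified
    dscreens = alt.expected_screens - ref.expected_screens
    per = dpy / 100_000.0
    d_statin = dpy * params.statin_incremental_cost
    d_screening = dscreens * params.cost_per_health_check
    return ProtocolComparison(
        protocol_name=alt.protocol.name,
        scheme=alt.protocol.scheme,
        delta_person_years=dpy,
        delta_screens=dscreens,
        events_prevented=per * params.events_prevented_rate,
        qalys_gained=per * params.qaly_gain_rate,
        diabetes_caused=per * params.diabetes_caused_rate,
        myopathy_caused=per * params.myopathy_caused_rate,
        delta_statin_cost=d_statin,
        delta_screening_cost=d_screening,
        delta_total_cost=d_statin + d_screening,
        total_screens=alt.expected_screens,
        intervals=dict(alt.protocol.interval_of),
    )


def select_optimal(
    comparisons: Sequence[ProtocolComparison],
) -> tuple[ProtocolComparison, bool]:
    """The protocol preventing the most events among those not increasing
    total costs; ties break toward the larger saving, then the smaller
    screening volume.  If none is cost-saving, the reference (the all-zero
    comparison) is returned flagged (second element False)."""
    if not comparisons:
        raise ValueError("no comparisons supplied")
    saving = [c for c in comparisons if c.cost_saving and c.events_prevented > 0]
    if not saving:
        ref = min(comparisons, key=lambda c: abs(c.delta_total_cost) + abs(c.delta_person_years))
        return ref, False
    best = max(
        saving,
        key=lambda c: (c.events_prevented, -c.delta_total_cost, -c.total_screens),
    )
    return best, True


def scale_initial_cohort(
    category_fractions: Mapping[str, float],
    population: float,
    ascvd_free_fraction: float = 1.0,
    unit: str = "millions",
) -> InitialCohort:
    """Apply a risk-category distribution to a population total.

    ``category_fractions`` covers the non-high categories (they may sum to
    less than 1; the remainder is the high-risk and excluded mass).  The
    population is first reduced to its ASCVD-free part.
    """
    if population < 0 or not (0.0 <= ascvd_free_fraction <= 1.0):
        raise ValueError("population must be >= 0 and free fraction in [0, 1]")
    fr = {k: float(v) for k, v in category_fractions.items()}
    if any(v < 0 for v in fr.values()):
        raise ValueError("fractions must be >= 0")
    if sum(fr.values()) > 1.0 + 1e-9:
        raise ValueError("non-high category fractions must sum to <= 1")
    base = population * ascvd_free_fraction
    return InitialCohort({k: base * v for k, v in fr.items()}, unit=unit)


def comparison_table(comparisons: Sequence[ProtocolComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.to_dict() for c in comparisons])
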