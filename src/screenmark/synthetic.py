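"""Synthetic panel-observed cohorts from a known generator CTMC.

Every downstream stage (risk classification, multistate fitting, screening
evaluation, health economics) is exercised on cohorts drawn from a fully
specified continuous-time Markov chain, so ground truth is available for
parameter-recovery experiments.  The observation scheme emulates a biobank
design: a baseline survey attended by everyone, a small number of resurveys
at roughly 4-5 year spacing each attended by a random subsample, exactly
dated absorbing events from registry linkage, and administrative censoring
at the end of follow-up.

A separate covariate simulator produces plausible risk-factor profiles
(age, blood pressures, smoking, diabetes, waist circumference, sex) that
drift over calendar time, for end-to-end tests through the risk equation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .msm import (
    OBS_CENSOR,
    OBS_EVENT,
    OBS_SCREEN,
    IntensityMatrix,
    PanelData,
    StateSpace,
)

__all__ = [
    "GeneratorSpec",
    "Path",
    "simulate_paths",
    "panel_observe",
    "simulate_panel",
    "CovariateModel",
    "simulate_covariate_cohort",
]


@dataclass(eq=False)
class GeneratorSpec:
    """Ground-truth data-generating process for a panel-observed cohort.

    ``true_Q`` is a conservative intensity matrix over ``state_labels``
    (non-high risk categories, the high category, then absorbing states);
    ``initial_distribution`` puts mass only on transient states.
    ``resurvey_fraction`` may be a scalar or one attendance probability per
    resurvey (the baseline visit is always attended).
    """

    state_labels: tuple[str, ...]
    true_Q: np.ndarray
    initial_distribution: np.ndarray
    n_subjects: int
    visit_schedule: tuple[float, ...] = (0.0, 4.0, 9.0)
    resurvey_fraction: "float | tuple[float, ...]" = 1.0
    horizon: float = 12.8
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_Q = np.asarray(self.true_Q, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        n = len(self.state_labels)
        if self.true_Q.shape != (n, n):
            raise ValueError("true_Q shape does not match state_labels")
        off = self.true_Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if np.any(np.abs(self.true_Q.sum(axis=1)) > 1e-10):
            raise ValueError("true_Q rows must sum to 0 (non-conservative generator)")
        sched = tuple(float(v) for v in self.visit_schedule)
        if sched[0] != 0.0 or np.any(np.diff(sched) <= 0):
            raise ValueError("visit_schedule must start at 0 and strictly increase")
        self.visit_schedule = sched
        fr = self.resurvey_fraction
        fr = (float(fr),) * (len(sched) - 1) if np.isscalar(fr) else tuple(fr)
        if len(fr) != len(sched) - 1 or any(not (0 < f <= 1) for f in fr):
            raise ValueError("need one attendance fraction in (0, 1] per resurvey")
        self.resurvey_fraction = fr
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if len(self.initial_distribution) != n:
            raise ValueError("initial_distribution length mismatch")
        if np.any(self.initial_distribution < 0) or not np.isclose(
            self.initial_distribution.sum(), 1.0
        ):
            raise ValueError("initial_distribution must be a probability vector")
        if off.max() > 0:  # a zero generator has no absorbing states at all
            absorbing = np.all(off == 0, axis=1)
            if self.initial_distribution[absorbing].sum() > 0:
                raise ValueError("initial mass on absorbing states")
            if self.initial_distribution[~absorbing].sum() == 0:
                raise ValueError("empty non-absorbing initial distribution")

    @property
    def space(self) -> StateSpace:
        return StateSpace.from_intensity_support(self.state_labels, self.true_Q)

    @property
    def intensity(self) -> IntensityMatrix:
        return IntensityMatrix(self.true_Q, self.space)

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["true_Q"] = self.true_Q.tolist()
        d["initial_distribution"] = self.initial_distribution.tolist()
        return d


@dataclass(eq=False)
class Path:
    """One subject's full event history: jump times and the states entered."""

    subject_id: int
    times: np.ndarray  # entry times, times[0] == 0
    states: np.ndarray  # state indices entered at those times

    def state_at(self, t: float) -> int:
        k = int(np.searchsorted(self.times, t, side="right")) - 1
        return int(self.states[k])


def simulate_paths(spec: GeneratorSpec, rng: np.random.Generator | None = None) -> list[Path]:
    """Forward-simulate full CTMC histories up to absorption or the horizon.

    Holding times in state ``i`` are exponential with rate ``-q_ii``; the
    next state follows the embedded-chain probabilities ``q_ij / -q_ii``.
    The same spec (hence seed) always yields identical histories.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    Q = spec.true_Q
    n = Q.shape[0]
    exit_rates = -np.diag(Q)
    jump_probs = []
    for i in range(n):
        if exit_rates[i] > 0:
            p = Q[i].copy()
            p[i] = 0.0
            jump_probs.append(p / exit_rates[i])
        else:
            jump_probs.append(None)

    starts = rng.choice(n, size=spec.n_subjects, p=spec.initial_distribution)
    paths = []
    for sid in range(spec.n_subjects):
        t, s = 0.0, int(starts[sid])
        times, states = [0.0], [s]
        while exit_rates[s] > 0:
            t += rng.exponential(1.0 / exit_rates[s])
            if t >= spec.horizon:
                break
            s = int(rng.choice(n, p=jump_probs[s]))
            times.append(t)
            states.append(s)
        paths.append(Path(sid, np.array(times), np.array(states, dtype=int)))
    return paths


def panel_observe(
    histories: Sequence[Path],
    spec: GeneratorSpec,
    exact_events: bool = True,
    exclusion: str = "none",
    rng: np.random.Generator | None = None,
) -> PanelData:
    """Reduce full histories to the panel observation scheme.

    Transient states are recorded only at attended visits; absorbing events
    are recorded at their exact time (``exact_events=False`` instead records
    the absorbing state as a screen at the next scheduled visit, the
    pure-panel convention); event-free subjects get a censoring record at
    the horizon.  ``exclusion='per_subject'`` drops subjects who attended no
    resurvey, mirroring a cohort defined by resurvey participation.
    """
    if exclusion not in ("none", "per_subject"):
        raise ValueError("exclusion must be 'none' or 'per_subject'")
    if rng is None:
        # independent stream from the path simulation, same spec seed
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]).entropy)
    space = spec.space
    absorbing = set(space.absorbing_indices.tolist())
    labels = spec.state_labels
    resurveys = spec.visit_schedule[1:]

    rows = []
    for path in histories:
        attend = rng.random(len(resurveys)) < np.asarray(spec.resurvey_fraction)
        if exclusion == "per_subject" and len(resurveys) and not attend.any():
            continue
        abs_mask = np.isin(path.states, list(absorbing))
        abs_time = float(path.times[abs_mask][0]) if abs_mask.any() else None
        abs_state = int(path.states[abs_mask][0]) if abs_mask.any() else None

        rows.append(
            {
                "subject_id": path.subject_id,
                "time_years": 0.0,
                "state": labels[path.state_at(0.0)],
                "obs_type": OBS_SCREEN,
            }
        )
        for v, att in zip(resurveys, attend):
            if abs_time is not None and v >= abs_time:
                break
            if att:
                rows.append(
                    {
                        "subject_id": path.subject_id,
                        "time_years": float(v),
                        "state": labels[path.state_at(v)],
                        "obs_type": OBS_SCREEN,
                    }
                )
        if abs_time is not None:
            if exact_events:
                rows.append(
                    {
                        "subject_id": path.subject_id,
                        "time_years": abs_time,
                        "state": labels[abs_state],
                        "obs_type": OBS_EVENT,
                    }
                )
            else:
                nxt = [v for v in spec.visit_schedule if v >= abs_time]
                if nxt:
                    rows.append(
                        {
                            "subject_id": path.subject_id,
                            "time_years": float(nxt[0]),
                            "state": labels[abs_state],
                            "obs_type": OBS_SCREEN,
                        }
                    )
        else:
            rows.append(
                {
                    "subject_id": path.subject_id,
                    "time_years": float(spec.horizon),
                    "state": "",
                    "obs_type": OBS_CENSOR,
                }
            )
    return PanelData(pd.DataFrame(rows))


def simulate_panel(
    spec: GeneratorSpec,
    exact_events: bool = True,
    exclusion: str = "none",
    p_male: float | None = None,
) -> PanelData:
    """Convenience: simulate_paths + panel_observe from one seed.

    With ``p_male`` set, a per-subject ``sex`` column ('male'/'female') is
    attached for stratified analyses; sex does not enter the dynamics.
    """
    rng_paths = np.random.default_rng(spec.seed)
    paths = simulate_paths(spec, rng_paths)
    rng_obs = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]).entropy)
    panel = panel_observe(paths, spec, exact_events=exact_events,
                          exclusion=exclusion, rng=rng_obs)
    if p_male is not None:
        rng_sex = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]).entropy)
        sex = np.where(
            rng_sex.random(spec.n_subjects) < p_male, "male", "female"
        )
        panel.records["sex"] = sex[panel.records["subject_id"].to_numpy()]
    return panel


def write_panel(panel: PanelData, csv_path, spec: GeneratorSpec, sidecar_path=None):
    """Write panel CSV plus a sidecar JSON recording the generating spec."""
    panel.to_csv(csv_path)
    if sidecar_path is None:
        sidecar_path = str(csv_path) + ".spec.json"
    with open(sidecar_path, "w") as fh:
        json.dump(spec.to_json_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# covariate cohort
# ---------------------------------------------------------------------------


@dataclass
class CovariateModel:
    """Joint distribution of risk-factor profiles for a middle-aged cohort.

    Continuous covariates are a correlated Gaussian vector (age truncated to
    [30, 79]); binary factors are thresholded latent normals correlated with
    age.  Between visits age advances deterministically, systolic pressure
    drifts upward, and binary factors may switch on with a constant hazard.
    """

    mean_age: float = 51.0
    sd_age: float = 11.0
    mean_sbp: float = 129.0
    sd_sbp: float = 19.0
    mean_dbp: float = 77.5
    sd_dbp: float = 10.5
    mean_waist: float = 79.0
    sd_waist: float = 9.5
    corr_age_sbp: float = 0.35
    corr_sbp_dbp: float = 0.65
    p_bp_medication: float = 0.105
    p_daily_smoker: float = 0.233
    p_diabetes: float = 0.026
    p_male: float = 0.39
    sbp_drift_per_year: float = 0.5
    onset_hazard: dict = field(
        default_factory=lambda: {"bp_medication": 0.012, "diabetes_history": 0.004}
    )


def simulate_covariate_cohort(
    n: int,
    seed: int,
    model: CovariateModel | None = None,
    visit_times: Sequence[float] = (0.0,),
) -> pd.DataFrame:
    """Seeded covariate table, one row per subject per visit.

    Columns: subject_id, visit_time, age, systolic_bp, diastolic_bp,
    bp_medication, daily_smoker, diabetes_history, waist_circumference, sex
    (1 = male).  Identical (n, seed, model) always yields an identical table.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    m = model or CovariateModel()
    cols = [
        "subject_id", "visit_time", "age", "systolic_bp", "diastolic_bp",
        "bp_medication", "daily_smoker", "diabetes_history",
        "waist_circumference", "sex",
    ]
    if n == 0:
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng(seed)

    # correlated continuous block: age, sbp, dbp, waist
    corr = np.array(
        [
            [1.0, m.corr_age_sbp, 0.25, 0.10],
            [m.corr_age_sbp, 1.0, m.corr_sbp_dbp, 0.20],
            [0.25, m.corr_sbp_dbp, 1.0, 0.20],
            [0.10, 0.20, 0.20, 1.0],
        ]
    )
    L = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, 4)) @ L.T
    age = np.clip(m.mean_age + m.sd_age * z[:, 0], 30.0, 79.0)
    sbp = np.maximum(m.mean_sbp + m.sd_sbp * z[:, 1], 80.0)
    dbp = np.maximum(m.mean_dbp + m.sd_dbp * z[:, 2], 45.0)
    waist = np.maximum(m.mean_waist + m.sd_waist * z[:, 3], 50.0)

    # binaries: latent normals sharing the age component
    def binary(p, rho_age):
        lat = rho_age * z[:, 0] + np.sqrt(1 - rho_age**2) * rng.standard_normal(n)
        from scipy.stats import norm

        return (lat > norm.ppf(1 - p)).astype(int)

    bp_med = binary(m.p_bp_medication, 0.3)
    diabetes = binary(m.p_diabetes, 0.25)
    smoker = binary(m.p_daily_smoker, 0.0)
    sex = (rng.random(n) < m.p_male).astype(int)

    frames = []
    state = {
        "bp_medication": bp_med.copy(),
        "diabetes_history": diabetes.copy(),
    }
    prev_t = 0.0
    for t in sorted(float(v) for v in visit_times):
        dt = t - prev_t
        if dt > 0:
            for name, hz in m.onset_hazard.items():
                switch = rng.random(n) < (1 - np.exp(-hz * dt))
                state[name] = np.maximum(state[name], switch.astype(int))
            prev_t = t
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.arange(n),
                    "visit_time": t,
                    "age": np.clip(age + t, 30.0, None),
                    "systolic_bp": sbp + m.sbp_drift_per_year * t,
                    "diastolic_bp": dbp,
                    "bp_medication": state["bp_medication"],
                    "daily_smoker": smoker,
                    "diabetes_history": state["diabetes_history"],
                    "waist_circumference": waist,
                    "sex": sex,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[cols]
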