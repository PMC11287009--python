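"""End-to-end orchestration: simulate or ingest panel data, fit the
multistate model, evaluate the protocol grids, compare against the uniform
reference and select the optimum.

A single flat configuration drives a run; outputs are machine-readable
(fitted model JSON, evaluation and comparison CSVs, an optimal-protocol
report) and every file records the seed and a hash of the configuration so
runs are auditable.  Identical configuration and seed give identical
numerical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .econ import EconParams, compare_to_reference, comparison_table, select_optimal
from .fixtures import ckb_like_generator, initial_cohort_from_population, table_econ_params
from .msm import IntensityMatrix, PanelData, StateSpace, fit, uncertainty_draws
from .screening import (
    REFERENCE_FOUR,
    REFERENCE_THREE,
    InitialCohort,
    enumerate_protocols,
    evaluation_generator,
    person_years_unidentified,
)
from .synthetic import GeneratorSpec, simulate_panel

log = logging.getLogger("screenmark")

__all__ = ["RunConfig", "run", "sex_stratified_run"]


@dataclass
class RunConfig:
    """Flat configuration for one analysis run.

    Exactly one of ``generator`` (simulate mode) / ``panel_csv`` (ingest
    mode) must be set.  ``schemes`` selects the protocol grids; the initial
    cohort defaults to the national risk-band populations.  ``n_draws``
    controls percentile confidence intervals on the comparisons (0 = point
    estimates only).
    """

    mode: str = "simulate"  # "simulate" | "ingest"
    # one generator, or one per scheme (the two cut-off schemes classify the
    # same cohort differently, so each needs its own generator state space)
    generator: "GeneratorSpec | dict[str, GeneratorSpec] | None" = None
    panel_csv: str | None = None
    schemes: tuple[str, ...] = ("three_category", "four_category")
    cohorts: dict | None = None  # scheme -> InitialCohort; default national
    cohort_unit_scale: float = 1e6  # counts in millions -> persons
    econ: EconParams = field(default_factory=table_econ_params)
    horizon: float = 10.0
    screening_mode: str = "continuous"
    exact_event_times: bool = True
    n_draws: int = 0
    seed: int = 0
    low_statin_cost: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if self.mode == "simulate" and self.generator is None:
            raise ValueError("simulate mode needs a generator spec")
        if self.mode == "ingest" and not self.panel_csv:
            raise ValueError("ingest mode needs a panel CSV path")
        if self.generator is not None and self.panel_csv:
            raise ValueError("give either a generator spec or a panel CSV, not both")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        gen = kw.pop("generator", None)
        if isinstance(gen, dict):
            if gen.get("fixture"):
                fixture_kw = {k: v for k, v in gen.items() if k != "fixture"}
                schemes = kw.get("schemes", ("three_category", "four_category"))
                if gen["fixture"] in ("ckb-like", "ckb_like"):
                    kw["generator"] = {
                        s: ckb_like_generator(s, **fixture_kw) for s in schemes
                    }
                else:
                    kw["generator"] = ckb_like_generator(gen["fixture"], **fixture_kw)
            else:
                gen["true_Q"] = np.asarray(gen["true_Q"], dtype=float)
                gen["initial_distribution"] = np.asarray(
                    gen["initial_distribution"], dtype=float
                )
                gen["state_labels"] = tuple(gen["state_labels"])
                kw["generator"] = GeneratorSpec(**gen)
        econ = kw.pop("econ", None)
        if isinstance(econ, dict):
            kw["econ"] = EconParams(**econ)
        if "schemes" in kw:
            kw["schemes"] = tuple(kw["schemes"])
        cohorts = kw.pop("cohorts", None)
        if isinstance(cohorts, dict):
            kw["cohorts"] = {
                scheme: InitialCohort(counts) for scheme, counts in cohorts.items()
            }
        return cls(**kw)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "to_json_dict"):
                return o.to_json_dict()
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)

        blob = json.dumps(self.__dict__, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _space_for(transient, absorbing) -> StateSpace:
    return StateSpace.ckb(
        non_high=[l for l in _order_states(transient) if l != "high"],
        high="high",
        absorbing=tuple(absorbing),
    )


def _simulate_unit(spec: GeneratorSpec, config: RunConfig):
    log.info("simulating %d subjects (seed %d)", spec.n_subjects, spec.seed)
    panel = simulate_panel(spec, exact_events=config.exact_event_times)
    space = _space_for(
        list(spec.space.transient_labels),
        [spec.state_labels[i] for i in spec.space.absorbing_indices],
    )
    return panel, space


def _ingest_unit(path):
    log.info("ingesting panel data from %s", path)
    panel = PanelData.from_csv(path)
    df = panel.records
    event_states = set(df.loc[df["obs_type"] == "event", "state"])
    labels = set(df.loc[df["obs_type"] != "censor", "state"])
    space = _space_for(_order_states(labels - event_states), sorted(event_states))
    return panel, space


def _schemes_supported(space: StateSpace, schemes) -> list[str]:
    out = []
    for s in schemes:
        ref = REFERENCE_THREE if s == "three_category" else REFERENCE_FOUR
        if set(ref.categories).issubset(space.labels):
            out.append(s)
    return out


def _load_units(config: RunConfig) -> list[dict]:
    """Fitting units: (tag, panel, state space, schemes it serves).

    A run on a CSV exported from a simulate run uses the same category
    structure and therefore reproduces the original results.
    """
    if config.mode == "ingest":
        panel, space = _ingest_unit(config.panel_csv)
        return [
            {"tag": "", "panel": panel, "space": space,
             "schemes": _schemes_supported(space, config.schemes)}
        ]
    gens = config.generator
    if isinstance(gens, GeneratorSpec):
        panel, space = _simulate_unit(gens, config)
        return [
            {"tag": "", "panel": panel, "space": space,
             "schemes": _schemes_supported(space, config.schemes)}
        ]
    units = []
    for scheme, spec in gens.items():
        if scheme not in config.schemes:
            continue
        panel, space = _simulate_unit(spec, config)
        units.append(
            {"tag": scheme, "panel": panel, "space": space,
             "schemes": _schemes_supported(space, (scheme,))}
        )
    return units


_CANONICAL_ORDER = [
    "low", "intermediate_low", "intermediate", "intermediate_high", "high",
]


def _order_states(labels) -> list[str]:
    known = [l for l in _CANONICAL_ORDER if l in labels]
    rest = sorted(set(labels) - set(known))
    return known + rest


def _scheme_pieces(scheme: str, config: RunConfig):
    reference = REFERENCE_THREE if scheme == "three_category" else REFERENCE_FOUR
    if config.cohorts and scheme in config.cohorts:
        cohort = config.cohorts[scheme]
    else:
        cohort = initial_cohort_from_population(scheme)
    if config.cohort_unit_scale != 1.0:
        cohort = InitialCohort(
            {k: v * config.cohort_unit_scale for k, v in cohort.counts.items()},
            unit="persons",
        )
    return reference, cohort


def _evaluate_scheme(Q: IntensityMatrix, scheme: str, config: RunConfig):
    reference, cohort = _scheme_pieces(scheme, config)
    Qe = evaluation_generator(Q)
    ref_res = person_years_unidentified(
        Qe, reference, cohort, horizon=config.horizon, mode=config.screening_mode
    )
    results = {}
    for proto in enumerate_protocols(scheme):
        results[proto.name] = person_years_unidentified(
            Qe, proto, cohort, horizon=config.horizon, mode=config.screening_mode
        )
    return ref_res, results


def run(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline and write artifacts under ``outdir``.

    Returns a summary dict with the fitted model, the comparison table and
    the optimal protocol.  Any stage failure aborts with a stage-named
    error message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    header = f"# screenmark {__version__} config_hash={chash} seed={config.seed}\n"

    stage = "load panel"
    try:
        units = _load_units(config)
        if not units:
            raise ValueError("no fitting unit matches the requested schemes")
        econ = (
            config.econ.with_low_statin_cost()
            if config.low_statin_cost
            else config.econ
        )
        comps = []
        eval_rows = []
        fitted_by_tag = {}
        for unit in units:
            tag, panel, space = unit["tag"], unit["panel"], unit["space"]
            suffix = f"_{tag}" if tag else ""
            if config.mode == "simulate":
                panel.to_csv(outdir / f"panel{suffix}.csv")

            stage = f"fit multistate model{' (' + tag + ')' if tag else ''}"
            log.info("fitting multistate model (%d records)", len(panel.records))
            fitted = fit(panel, space, exact_event_times=config.exact_event_times)
            fitted_by_tag[tag] = fitted
            with open(outdir / f"fitted_model{suffix}.json", "w") as fh:
                json.dump(
                    {"config_hash": chash, "seed": config.seed,
                     **fitted.to_json_dict()},
                    fh, indent=2,
                )
            if not fitted.converged:
                log.warning("fit did not converge: %s", fitted.report)

            stage = "evaluate protocols"
            for scheme in unit["schemes"]:
                ref_res, results = _evaluate_scheme(fitted.Q, scheme, config)
                for name, res in results.items():
                    comps.append(compare_to_reference(res, ref_res, econ))
                    eval_rows.append(
                        {
                            "protocol": name,
                            "scheme": scheme,
                            "person_years_unidentified": res.person_years_unidentified,
                            "expected_screens": res.expected_screens,
                            "identified_mass": res.identified_mass,
                            "absorbed_mass": res.absorbed_mass,
                        }
                    )

            stage = "uncertainty propagation"
            if config.n_draws > 0:
                comps = _attach_intervals(
                    fitted, comps, config, econ, unit["schemes"]
                )
        eval_df = pd.DataFrame(eval_rows)
        _write_csv(eval_df, outdir / "protocol_results.csv", header)

        stage = "compare and select"
        comp_df = comparison_table(comps)
        _write_csv(comp_df, outdir / "comparisons.csv", header)
        with open(outdir / "comparisons.json", "w") as fh:
            json.dump(
                {"config_hash": chash, "seed": config.seed,
                 "comparisons": [c.to_dict() for c in comps]},
                fh, indent=2,
            )
        best, dominated = select_optimal(comps)
        report = {
            "config_hash": chash,
            "seed": config.seed,
            "version": __version__,
            "optimal_protocol": best.protocol_name,
            "scheme": best.scheme,
            "reference_dominated": dominated,
            "events_prevented": best.events_prevented,
            "qalys_gained": best.qalys_gained,
            "delta_total_cost": best.delta_total_cost,
            "convergence": {
                tag or "model": fm.report for tag, fm in fitted_by_tag.items()
            },
            "converged": all(fm.converged for fm in fitted_by_tag.values()),
        }
        with open(outdir / "optimal_protocol.json", "w") as fh:
            json.dump(report, fh, indent=2)
        log.info(
            "optimal protocol: %s (%s); events prevented %.0f, cost delta %.3g",
            best.protocol_name, best.scheme, best.events_prevented,
            best.delta_total_cost,
        )
        return {"fitted": fitted_by_tag, "comparisons": comps, "optimal": best,
                "reference_dominated": dominated, "config_hash": chash}
    except Exception as err:
        (outdir / "INVALID").write_text(f"stage: {stage}\nerror: {err}\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err


def _attach_intervals(fitted, comps, config, econ, schemes, level: float = 0.95):
    """Percentile intervals from parametric draws propagated through the
    screening evaluator and the economic layer, for the given schemes."""
    draws = uncertainty_draws(fitted, config.n_draws, seed=config.seed + 1)
    mine = [c for c in comps if c.scheme in schemes and c.ci is None]
    samples: dict[str, dict[str, list[float]]] = {
        c.protocol_name + "/" + c.scheme: {
            "delta_person_years": [], "events_prevented": [], "qalys_gained": [],
            "delta_total_cost": [],
        }
        for c in mine
    }
    for Qd in draws:
        for scheme in schemes:
            ref_res, results = _evaluate_scheme(Qd, scheme, config)
            for name, res in results.items():
                c = compare_to_reference(res, ref_res, econ)
                rec = samples[name + "/" + scheme]
                rec["delta_person_years"].append(c.delta_person_years)
                rec["events_prevented"].append(c.events_prevented)
                rec["qalys_gained"].append(c.qalys_gained)
                rec["delta_total_cost"].append(c.delta_total_cost)
    a = (1 - level) / 2
    for c in mine:
        rec = samples[c.protocol_name + "/" + c.scheme]
        c.ci = {
            k: (
                float(np.quantile(v, a)),
                float(np.quantile(v, 1 - a)),
            )
            for k, v in rec.items()
        }
    return comps


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def sex_stratified_run(config: RunConfig, outdir) -> dict:
    """Fit and evaluate separately per sex stratum of the panel data.

    Simulate mode attaches sexes at a 39% male share with identical
    dynamics; ingest mode requires a ``sex`` column.  A stratum without
    absorbing events is reported with a warning instead of a fit.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.mode == "simulate":
        gen = config.generator
        if isinstance(gen, dict):  # stratify the first requested scheme
            gen = gen[config.schemes[0]]
        panel = simulate_panel(
            gen, exact_events=config.exact_event_times, p_male=0.39
        )
    else:
        panel, _ = _ingest_unit(config.panel_csv)
    if "sex" not in panel.records.columns:
        raise ValueError("sex-stratified run needs a 'sex' column in the panel")

    out = {}
    for sex in ("female", "male"):
        sub = PanelData(panel.records[panel.records["sex"] == sex].copy())
        subdir = outdir / sex
        if len(sub.records) == 0 or (sub.records["obs_type"] == "event").sum() == 0:
            log.warning("stratum %s has no absorbing events; skipping fit", sex)
            subdir.mkdir(parents=True, exist_ok=True)
            (subdir / "WARNING").write_text("no absorbing events in stratum\n")
            out[sex] = None
            continue
        cfg = RunConfig(
            mode="ingest", panel_csv="unused", schemes=config.schemes,
            cohorts=config.cohorts, cohort_unit_scale=config.cohort_unit_scale,
            econ=config.econ, horizon=config.horizon,
            screening_mode=config.screening_mode,
            exact_event_times=config.exact_event_times,
            n_draws=config.n_draws, seed=config.seed,
            low_statin_cost=config.low_statin_cost,
        )
        # run the stages directly on the stratum panel
        out[sex] = _run_on_panel(cfg, sub, subdir)
    return out


def _run_on_panel(config: RunConfig, panel: PanelData, outdir) -> dict:
    cfg_dir = Path(outdir)
    cfg_dir.mkdir(parents=True, exist_ok=True)
    tmp = cfg_dir / "panel.csv"
    panel.to_csv(tmp)
    cfg = RunConfig(
        mode="ingest", panel_csv=str(tmp), schemes=config.schemes,
        cohorts=config.cohorts, cohort_unit_scale=config.cohort_unit_scale,
        econ=config.econ, horizon=config.horizon,
        screening_mode=config.screening_mode,
        exact_event_times=config.exact_event_times,
        n_draws=config.n_draws, seed=config.seed,
        low_statin_cost=config.low_statin_cost,
    )
    return run(cfg, cfg_dir)
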