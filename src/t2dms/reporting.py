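"""Pipeline assembly, validation against reference series, run manifests.

`run_pipeline` executes the whole chain -- generate register, ascertain
cases, estimate and smooth transition probabilities, build the four
scenarios, project to the horizon, compute health expectancies -- and
writes tidy CSV outputs plus a manifest sufficient to reproduce the run.

`validate_against_reference` compares any model (year, value) series with
an external reference shaped like Human Mortality Database life-table
extracts or Diabetes-in-Finland count tables (two columns: year, value);
inside the test suite the reference is the generator's own ground truth.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, engine, health_expectancy, scenarios_paf, synth_register, transitions
from .config import PipelineConfig
from .probset import AGE_MIN, TransitionProbabilitySet


@dataclass
class ValidationReport:
    source: str
    years: list[int]
    ape: list[float]          # absolute percentage error per year, in %
    threshold_pct: float = 5.0

    def __post_init__(self) -> None:
        if not self.years:
            raise ValueError("no overlapping years to compare")

    @property
    def mape(self) -> float:
        return float(np.mean(self.ape))

    @property
    def max_ape(self) -> float:
        return float(np.max(self.ape))

    @property
    def passed(self) -> bool:
        return self.mape <= self.threshold_pct

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "years": self.years,
            "mape_pct": self.mape,
            "max_ape_pct": self.max_ape,
            "threshold_pct": self.threshold_pct,
            "passed": self.passed,
        }


def validate_against_reference(
    model_series: pd.DataFrame,
    reference: pd.DataFrame | str | Path,
    source: str = "reference",
    threshold_pct: float = 5.0,
) -> ValidationReport:
    """Absolute percentage errors of a model (year, value) series.

    ``reference`` is a data frame or CSV with columns ``year`` and
    ``value``.  Only overlapping years are compared; none is an error.
    """
    if not isinstance(reference, pd.DataFrame):
        reference = pd.read_csv(reference)
    merged = model_series.merge(reference, on="year", suffixes=("_model", "_ref"))
    if merged.empty:
        raise ValueError("model and reference series share no years")
    ape = (
        100.0
        * (merged["value_model"] - merged["value_ref"]).abs()
        / merged["value_ref"].abs()
    )
    return ValidationReport(
        source=source,
        years=merged["year"].astype(int).tolist(),
        ape=ape.tolist(),
        threshold_pct=threshold_pct,
    )


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    scenarios: list[str]
    version: str
    timestamp: str = field(default="")

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory results of one pipeline run."""

    config: PipelineConfig
    register: pd.DataFrame
    truth: pd.DataFrame
    ascertainment: pd.DataFrame
    counts: pd.DataFrame
    probs: TransitionProbabilitySet
    scenario_probs: dict[str, TransitionProbabilitySet]
    trajectories: dict[str, engine.PopulationTrajectory]
    prevalence: dict[str, pd.DataFrame]
    health_expectancy: dict[str, pd.DataFrame]
    inequality: dict[str, pd.DataFrame]
    paf: scenarios_paf.PAFSchedule
    validation: list[ValidationReport]
    manifest: RunManifest


def truth_prevalence_series(truth: pd.DataFrame, years) -> pd.DataFrame:
    """Ground-truth prevalent T2D count per year (start-of-year state)."""
    rows = []
    inc = truth["incidence_year"].to_numpy()
    death = truth["death_year"].fillna(np.inf).to_numpy()
    entry = truth["entry_year"].to_numpy()
    for y in years:
        alive = (entry <= y) & (death >= y)
        rows.append({"year": int(y), "value": int(((inc < y) & alive).sum())})
    return pd.DataFrame(rows)


def ascertained_prevalence_series(
    register: pd.DataFrame, ascertainment: pd.DataFrame, years
) -> pd.DataFrame:
    """Register-estimated prevalent count per year, from ascertained cases."""
    inc = register["person_id"].map(ascertainment.set_index("person_id")["incidence_year"])
    has = (inc < register["year"]).to_numpy()
    per_year = register.loc[has].groupby("year").size()
    return pd.DataFrame(
        {"year": list(years), "value": [int(per_year.get(y, 0)) for y in years]}
    )


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full chain; optionally write CSV outputs to ``out_dir``."""
    stage = "generate"
    try:
        schedule = synth_register.GroundTruthSchedule(cfg.schedule)
        register, truth = synth_register.generate_register(cfg.register, schedule, cfg.seed)

        stage = "ascertain"
        asc = synth_register.ascertain_register(register)

        stage = "estimate"
        counts = synth_register.aggregate_counts(register, asc)
        raw = transitions.estimate_transition_probabilities(counts)
        smoothed = transitions.smooth_over_age(
            raw, min_at_risk=cfg.projection.min_at_risk_smooth, on_missing="skip"
        )
        probs = transitions.fill_missing(smoothed)

        stage = "scenarios"
        pcfg = cfg.projection
        scen_probs = scenarios_paf.build_all_scenarios(
            probs,
            cfg.obesity,
            fit_start=pcfg.mortality_fit_start,
            fit_end=pcfg.mortality_fit_end,
            trend_from=pcfg.incidence_trend_from,
            trend_to=pcfg.incidence_trend_to,
            exclude=pcfg.exclude_years,
            horizon=pcfg.horizon,
            names=cfg.scenarios,
        )
        paf = scenarios_paf.compute_paf(cfg.obesity)

        stage = "project"
        init = engine.initial_state_from_register(
            register, asc, truth, year=pcfg.start_year
        )
        n_entrants = pcfg.entrants_per_year
        if n_entrants is None:
            last = register[register["year"] == cfg.register.end_year]
            n_entrants = int((last["year"] - last["birth_year"] == AGE_MIN).sum())
        ent = engine.EntrantSchedule.constant(
            range(pcfg.start_year + 1, pcfg.horizon + 1), float(n_entrants)
        )
        trajectories = {
            name: engine.project(init, sp, ent, horizon=pcfg.horizon)
            for name, sp in scen_probs.items()
        }
        prevalence = {
            name: engine.prevalence_table(tr, years=cfg.le_years)
            for name, tr in trajectories.items()
        }

        stage = "le"
        het = {
            name: health_expectancy.health_expectancy_table(
                trajectories[name], scen_probs[name], years=cfg.le_years
            )
            for name in trajectories
        }
        ineq = {name: health_expectancy.inequality_summary(t) for name, t in het.items()}

        stage = "validate"
        hist_years = range(cfg.register.start_year + 1, cfg.register.end_year + 1)
        model_prev = ascertained_prevalence_series(register, asc, hist_years)
        truth_prev = truth_prevalence_series(truth, hist_years)
        validation = [
            validate_against_reference(
                model_prev, truth_prev, source="synthetic-ground-truth-prevalence"
            )
        ]

        manifest = RunManifest(
            config_hash=_config_hash(cfg),
            seed=cfg.seed,
            scenarios=list(cfg.scenarios),
            version=__version__,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err

    result = PipelineResult(
        config=cfg,
        register=register,
        truth=truth,
        ascertainment=asc,
        counts=counts,
        probs=probs,
        scenario_probs=scen_probs,
        trajectories=trajectories,
        prevalence=prevalence,
        health_expectancy=het,
        inequality=ineq,
        paf=paf,
        validation=validation,
        manifest=manifest,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Write the tables a publication would print, as tidy CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.counts.to_csv(out / "strata_counts.csv", index=False)
    result.probs.to_csv(out / "transition_probabilities.csv")
    result.paf.to_frame().assign(assumptions=result.paf.label).to_csv(
        out / "paf.csv", index=False
    )
    for name, sp in result.scenario_probs.items():
        sp.to_csv(out / f"probabilities_{name}.csv")
    for name, tab in result.prevalence.items():
        tab.to_csv(out / f"prevalence_{name}.csv", index=False)
    for name, tab in result.health_expectancy.items():
        tab.to_csv(out / f"life_expectancy_{name}.csv", index=False)
    for name, tab in result.inequality.items():
        tab.to_csv(out / f"inequality_{name}.csv", index=False)
    series = []
    for name, tr in result.trajectories.items():
        for s in tr.states:
            per_q = s.n_t2d.sum(axis=(0, 1))
            for qi, v in enumerate(per_q):
                series.append(
                    {"scenario": name, "year": s.year, "quintile": qi + 1, "n_t2d": v}
                )
    pd.DataFrame(series).to_csv(out / "prevalence_series.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {
                **result.manifest.to_dict(),
                "validation": [v.to_dict() for v in result.validation],
            },
            fh,
            indent=2,
        )
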