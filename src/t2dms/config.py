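"""Run configuration: dataclasses plus YAML round trip.

A single :class:`PipelineConfig` drives the whole pipeline (register
generation, trend fitting, scenario assumptions, projection horizon).  The
seed is mandatory: every stochastic component draws from a generator seeded
from it, so a config fully determines a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RegisterConfig:
    """Synthetic register: cohort sizes, follow-up window, pathway mix."""

    n_persons: int = 60_000            # initial cohort alive in start_year
    start_year: int = 1995
    end_year: int = 2019
    entrant_rate: float = 0.021        # 30-year-old entrants per year, as share of n_persons
    initial_prevalence_scale: float = 1.0
    # share of true cases routed through each ascertainment pathway (1..5);
    # pathways 4 and 5 need age >= 40 at onset and fall back to 3 otherwise
    pathway_shares: tuple[float, ...] = (0.15, 0.25, 0.40, 0.10, 0.10)
    decoy_insulin_fraction: float = 0.01   # insulin-only users who are not T2D
    income_sigma: float = 0.55         # log-sd of equivalised income
    income_median: float = 24_000.0    # median equivalised income (EUR/year)
    income_growth: float = 0.015       # nominal growth per calendar year


@dataclass
class ScheduleConfig:
    """Ground-truth transition schedule planted by the generator.

    Incidence rises to a peak after age 60, is higher for men and for lower
    income quintiles, carries a 2007-2010 diagnosis bump and declines after
    2011.  Mortality is Gompertz in age with an income gradient, declines
    over calendar time, and carries a T2D excess that shrinks with age.
    """

    # incidence: Gaussian-in-age on log scale, peaked after 60
    inc_peak_m: float = 0.013
    inc_peak_f: float = 0.010
    inc_peak_age: float = 68.0
    inc_age_width: float = 26.0
    inc_quintile_log_gradient: float = 0.13   # Q5 vs Q3 on log scale
    inc_peak_age_gradient: float = 2.0        # years earlier per quintile step (deprived earlier)
    inc_pre_trend: float = 0.01               # log slope per year before 2007
    bump_start: int = 2007
    bump_end: int = 2010
    bump_multiplier: float = 1.25
    decline_start: int = 2011
    inc_decline_rate: float = 0.01            # log decline per year from 2011
    incidence_scale: float = 1.0
    # mortality: Gompertz, calendar decline, diminishing T2D excess
    mort30_m: float = 0.0007
    mort30_f: float = 0.00035
    gompertz_slope: float = 0.093
    mort_quintile_log_gradient: float = 0.09
    mort_grad_fade_age: float = 95.0          # income gradient fades linearly to 0 by this age
    mort_decline_rate: float = 0.02
    mort_ref_year: int = 2019
    t2d_excess_at30: float = 2.0
    t2d_excess_age_tau: float = 30.0


@dataclass
class ObesityAssumptions:
    """Obesity exposure driving the PAF scenarios.

    Prevalence and relative risks are constant across income groups; the
    shipped defaults are illustrative placeholders, labelled as such in all
    outputs.
    """

    p_obesity_m: float = 0.25
    p_obesity_f: float = 0.25
    rr_incidence: float = 3.0
    rr_mortality: float = 1.5
    label: str = "illustrative-default"


@dataclass
class ProjectionConfig:
    start_year: int = 2019
    horizon: int = 2040
    entrants_per_year: int | None = None   # None -> use register's age-30 count
    mortality_fit_start: int = 1995
    mortality_fit_end: int = 2018
    incidence_trend_from: int = 2011
    incidence_trend_to: int = 2019
    exclude_years: tuple[int, int] = (2007, 2010)
    min_at_risk_smooth: float = 500.0


@dataclass
class PipelineConfig:
    seed: int
    register: RegisterConfig = field(default_factory=RegisterConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    obesity: ObesityAssumptions = field(default_factory=ObesityAssumptions)
    projection: ProjectionConfig = field(default_factory=ProjectionConfig)
    scenarios: tuple[str, ...] = ("baseline", "A", "B", "C")
    le_years: tuple[int, ...] = (2020, 2030, 2040)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        if "seed" not in d:
            raise ValueError("config must set a seed")
        kw = dict(d)
        for key, sub in (
            ("register", RegisterConfig),
            ("schedule", ScheduleConfig),
            ("obesity", ObesityAssumptions),
            ("projection", ProjectionConfig),
        ):
            if key in kw and isinstance(kw[key], dict):
                kw[key] = sub(**{k: _detuple(sub, k, v) for k, v in kw[key].items()})
        for key in ("scenarios", "le_years"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)


def _detuple(klass, key, value):
    """YAML loads tuples as lists; restore tuple-typed fields."""
    if isinstance(value, list):
        return tuple(value)
    return value


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(cfg.to_dict()), fh, sort_keys=False)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
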