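"""Obesity population attributable fraction and the four scenarios.

The counterfactual scenarios modify projected transition probabilities for
years after 2019:

* **baseline** -- incidence frozen at its 2019 level, mortality follows its
  projected trend;
* **A** -- incidence continues the post-2011 decline;
* **B** -- obesity-related excess risk eliminated: scenario A's future
  incidence and T2D mortality multiplied by ``1 - PAF``;
* **C** -- obesity's contribution doubled: multiplied by ``1 + PAF``.

PAF uses Levin's formula for a dichotomous exposure,
``PAF = p (RR - 1) / (1 + p (RR - 1))``, computed separately for the
incidence and the T2D-mortality relative risks and per gender.  Obesity
prevalence and relative risks are assumed identical across income groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ObesityAssumptions
from .probset import GENDERS, TransitionProbabilitySet
from . import transitions


@dataclass(frozen=True)
class PAFSchedule:
    """PAF per gender for incidence and for T2D mortality."""

    incidence: dict[str, float]
    mortality: dict[str, float]
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gender": g, "paf_incidence": self.incidence[g], "paf_mortality": self.mortality[g]}
            for g in GENDERS
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScenarioSpec:
    """Named counterfactual: incidence rule plus post-2019 multiplier sign."""

    name: str  # baseline | A | B | C

    @property
    def multiplier_sign(self) -> int:
        return {"baseline": 0, "A": 0, "B": -1, "C": +1}[self.name]


def levin_paf(p_exposure: float, relative_risk: float) -> float:
    """Levin's attributable fraction for a dichotomous exposure."""
    if not 0.0 <= p_exposure <= 1.0:
        raise ValueError(f"exposure prevalence {p_exposure} outside [0, 1]")
    if relative_risk < 0:
        raise ValueError(f"relative risk {relative_risk} must be non-negative")
    excess = p_exposure * (relative_risk - 1.0)
    return excess / (1.0 + excess)


def compute_paf(assumptions: ObesityAssumptions) -> PAFSchedule:
    """PAF schedule from obesity prevalence and relative risks per gender."""
    prev = {"M": assumptions.p_obesity_m, "F": assumptions.p_obesity_f}
    return PAFSchedule(
        incidence={g: levin_paf(prev[g], assumptions.rr_incidence) for g in GENDERS},
        mortality={g: levin_paf(prev[g], assumptions.rr_mortality) for g in GENDERS},
        label=assumptions.label,
    )


def apply_scenario(
    probs_a: TransitionProbabilitySet,
    spec: ScenarioSpec,
    paf: PAFSchedule,
    after_year: int = 2019,
) -> TransitionProbabilitySet:
    """Apply the scenario multiplier to years strictly after ``after_year``.

    Incidence and T2D mortality are multiplied by ``1 -/+ PAF`` (clamped to
    [0, 1]); free-state mortality and all historical years are untouched.
    """
    out = probs_a.copy()
    sign = spec.multiplier_sign
    if sign == 0:
        return out
    future = out.years > after_year
    for gi, g in enumerate(GENDERS):
        m_inc = 1.0 + sign * paf.incidence[g]
        m_mort = 1.0 + sign * paf.mortality[g]
        out.p_inc[:, gi, :, future] = np.clip(out.p_inc[:, gi, :, future] * m_inc, 0.0, 1.0)
        out.p_m_t2d[:, gi, :, future] = np.clip(out.p_m_t2d[:, gi, :, future] * m_mort, 0.0, 1.0)
    out.enforce_terminal_age()
    return out


def build_all_scenarios(
    hist_probs: TransitionProbabilitySet,
    assumptions: ObesityAssumptions,
    fit_start: int = 1995,
    fit_end: int = 2018,
    trend_from: int = 2011,
    trend_to: int = 2018,
    exclude: tuple[int, int] | None = (2007, 2010),
    horizon: int = 2040,
    names: tuple[str, ...] = ("baseline", "A", "B", "C"),
    stabilize_baseline: bool = True,
) -> dict[str, TransitionProbabilitySet]:
    """Build the full scenario map from historical probabilities.

    Mortality projection is shared by every scenario; the scenarios differ
    only in future incidence (and, for B/C, future T2D mortality).  With
    ``stabilize_baseline`` the 2019 incidence level the baseline freezes is
    a trend-aligned recent mean rather than the raw 2019 slice.
    """
    mort = transitions.fit_mortality_trend(
        hist_probs, fit_start=fit_start, fit_end=fit_end, horizon=horizon
    )
    paf = compute_paf(assumptions)
    out: dict[str, TransitionProbabilitySet] = {}
    scen_a = None
    if {"A", "B", "C"} & set(names):
        scen_a = transitions.fit_incidence_trend_scenarioA(
            mort, trend_from=trend_from, trend_to=trend_to, exclude=exclude, horizon=horizon
        )
        scen_a = transitions.enforce_joint_constraint(scen_a)
    for name in names:
        if name == "baseline":
            src = mort
            if stabilize_baseline:
                src = transitions.stabilize_incidence_level(
                    mort, at_year=fit_end + 1, trend_from=trend_from, exclude=exclude
                )
            base = transitions.hold_incidence_constant(src, at_year=fit_end + 1)
            out[name] = transitions.enforce_joint_constraint(base)
        elif name == "A":
            out[name] = scen_a
        elif name in ("B", "C"):
            out[name] = transitions.enforce_joint_constraint(
                apply_scenario(scen_a, ScenarioSpec(name), paf, after_year=fit_end + 1)
            )
        else:
            raise ValueError(f"unknown scenario {name!r}")
        out[name].validate()
    return out
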