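"""Cohort-component multi-state projection engine.

Advances expected state-occupancy counts (free of T2D, with T2D) through
one-year steps from the launch year to the horizon.  The update rule for a
cell at age ``a`` in year ``t`` with start-of-year counts ``N_free`` and
``N_t2d``::

    deaths_free = N_free * p_m_free
    incident    = N_free * p_inc
    deaths_t2d  = N_t2d  * p_m_t2d
    N_free(a+1, t+1) = N_free - deaths_free - incident
    N_t2d(a+1, t+1)  = N_t2d - deaths_t2d + incident

Incident cases are not exposed to T2D mortality in their incidence year
(the transition happens at the year boundary).  A new cohort of disease-
free 30-year-olds enters each year.  Counts are real-valued expected
values; :func:`microsim_oracle` replays the same dynamics with individual
Bernoulli draws as an independent stochastic check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .probset import AGE_MAX, AGE_MIN, GENDERS, QUINTILES, TransitionProbabilitySet

_SHAPE = (AGE_MAX - AGE_MIN + 1, len(GENDERS), len(QUINTILES))


@dataclass
class StateVector:
    """Occupancy counts per (age, gender, quintile) at the start of a year."""

    year: int
    n_free: np.ndarray
    n_t2d: np.ndarray

    def __post_init__(self) -> None:
        self.n_free = np.asarray(self.n_free, dtype=float)
        self.n_t2d = np.asarray(self.n_t2d, dtype=float)
        for arr in (self.n_free, self.n_t2d):
            if arr.shape != _SHAPE:
                raise ValueError(f"state arrays must have shape {_SHAPE}")
            if not np.isfinite(arr).all() or (arr < -1e-9).any():
                raise ValueError("state counts must be finite and non-negative")

    @property
    def total(self) -> float:
        return float(self.n_free.sum() + self.n_t2d.sum())

    def copy(self) -> "StateVector":
        return StateVector(self.year, self.n_free.copy(), self.n_t2d.copy())


@dataclass
class EntrantSchedule:
    """Disease-free 30-year-olds entering per (year, gender, quintile)."""

    counts: dict[int, np.ndarray]  # year -> (gender, quintile) array

    @classmethod
    def constant(
        cls,
        years,
        total_per_year: float,
        quintile_shares=(0.2, 0.2, 0.2, 0.2, 0.2),
        gender_shares=(0.5, 0.5),
    ) -> "EntrantSchedule":
        shares = np.outer(gender_shares, quintile_shares)
        if not np.isclose(shares.sum(), 1.0):
            raise ValueError("gender x quintile shares must sum to 1")
        return cls({int(y): total_per_year * shares for y in years})

    def for_year(self, year: int) -> np.ndarray:
        return self.counts.get(int(year), np.zeros((len(GENDERS), len(QUINTILES))))


@dataclass
class PopulationTrajectory:
    """Ordered state vectors plus the flows that produced each step."""

    states: list[StateVector] = field(default_factory=list)
    flows: list[dict] = field(default_factory=list)  # aligned with states[:-1]

    @property
    def years(self) -> list[int]:
        return [s.year for s in self.states]

    def state_at(self, year: int) -> StateVector:
        for s in self.states:
            if s.year == year:
                return s
        raise KeyError(f"year {year} not in trajectory ({self.years[0]}..{self.years[-1]})")

    def to_frame(self) -> pd.DataFrame:
        recs = []
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
        for s in self.states:
            for gi, g in enumerate(GENDERS):
                for qi, q in enumerate(QUINTILES):
                    recs.append(
                        pd.DataFrame(
                            {
                                "year": s.year,
                                "gender": g,
                                "quintile": q,
                                "age": ages,
                                "n_free": s.n_free[:, gi, qi],
                                "n_t2d": s.n_t2d[:, gi, qi],
                            }
                        )
                    )
        return pd.concat(recs, ignore_index=True)


def step(
    state: StateVector,
    probs: TransitionProbabilitySet,
    entrants_next: np.ndarray | None = None,
) -> tuple[StateVector, dict]:
    """Advance the population one year; returns (next state, flow tallies).

    Flows are per-cell arrays of incident cases and deaths by state for the
    year being stepped over.  People at the terminal age die within the
    year (their mortality is 1), closing the life table.
    """
    p = probs.year_slice(state.year)
    for name, arr in p.items():
        if np.isnan(arr[(state.n_free > 0) | (state.n_t2d > 0)]).any():
            raise ValueError(f"{name} undefined for occupied cells in {state.year}")
    s = p["p_inc"] + p["p_m_free"]
    if np.nanmax(s) > 1.0 + 1e-9:
        raise ValueError("p_inc + p_m_free exceeds 1")

    deaths_free = state.n_free * np.nan_to_num(p["p_m_free"])
    incident = state.n_free * np.nan_to_num(p["p_inc"])
    deaths_t2d = state.n_t2d * np.nan_to_num(p["p_m_t2d"])

    surv_free = state.n_free - deaths_free - incident
    surv_t2d = state.n_t2d - deaths_t2d + incident
    assert (surv_free > -1e-9).all() and (surv_t2d > -1e-9).all()

    n_free = np.zeros(_SHAPE)
    n_t2d = np.zeros(_SHAPE)
    # age shift; the terminal age pools nothing because mortality there is 1
    n_free[1:] = surv_free[:-1]
    n_t2d[1:] = surv_t2d[:-1]
    n_free[-1] += surv_free[-1]
    n_t2d[-1] += surv_t2d[-1]
    if entrants_next is not None:
        n_free[0] = np.maximum(entrants_next, 0.0)

    flows = {
        "year": state.year,
        "incident": incident,
        "deaths_free": deaths_free,
        "deaths_t2d": deaths_t2d,
    }
    return StateVector(state.year + 1, np.clip(n_free, 0, None), np.clip(n_t2d, 0, None)), flows


def project(
    initial_state: StateVector,
    scenario_probs: TransitionProbabilitySet,
    entrants: EntrantSchedule,
    horizon: int = 2040,
) -> PopulationTrajectory:
    """Deterministic projection from the initial year to ``horizon``."""
    if initial_state.year > horizon:
        raise ValueError("initial state is beyond the horizon")
    traj = PopulationTrajectory(states=[initial_state.copy()])
    state = initial_state
    while state.year < horizon:
        nxt, flows = step(state, scenario_probs, entrants.for_year(state.year + 1))
        traj.flows.append(flows)
        traj.states.append(nxt)
        state = nxt
    return traj


def microsim_oracle(
    initial_state: StateVector,
    scenario_probs: TransitionProbabilitySet,
    entrants: EntrantSchedule,
    horizon: int,
    seed: int,
    n_agents: int = 100_000,
) -> PopulationTrajectory:
    """Individual-level Bernoulli replay of the same dynamics.

    ``n_agents`` agents are allocated to cells proportionally to the
    initial state (largest-remainder rounding); entrants are scaled by the
    same factor.  Occupancy counts are scaled back to population units, so
    the output converges to :func:`project` as ``n_agents`` grows.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    rng = np.random.default_rng(seed)
    scale = initial_state.total / n_agents

    def _allocate(weights: np.ndarray, n: int) -> np.ndarray:
        flat = weights.ravel()
        if flat.sum() <= 0:
            return np.zeros_like(flat, dtype=int).reshape(weights.shape)
        quota = flat / flat.sum() * n
        base = np.floor(quota).astype(int)
        rem = n - base.sum()
        if rem > 0:
            order = np.argsort(-(quota - base))
            base[order[:rem]] += 1
        return base.reshape(weights.shape)

    counts_free = _allocate(initial_state.n_free, int(round(initial_state.n_free.sum() / scale)))
    counts_t2d = _allocate(initial_state.n_t2d, int(round(initial_state.n_t2d.sum() / scale)))

    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    cell_age, cell_g, cell_q = np.meshgrid(
        ages, np.arange(2), np.arange(5), indexing="ij"
    )
    agent_age = np.concatenate(
        [np.repeat(cell_age.ravel(), counts_free.ravel()), np.repeat(cell_age.ravel(), counts_t2d.ravel())]
    )
    agent_g = np.concatenate(
        [np.repeat(cell_g.ravel(), counts_free.ravel()), np.repeat(cell_g.ravel(), counts_t2d.ravel())]
    )
    agent_q = np.concatenate(
        [np.repeat(cell_q.ravel(), counts_free.ravel()), np.repeat(cell_q.ravel(), counts_t2d.ravel())]
    )
    agent_state = np.concatenate(
        [np.zeros(counts_free.sum(), dtype=int), np.ones(counts_t2d.sum(), dtype=int)]
    )  # 0 free, 1 t2d, 2 dead

    def _occupancy(year: int) -> StateVector:
        n_free = np.zeros(_SHAPE)
        n_t2d = np.zeros(_SHAPE)
        for st, arr in ((0, n_free), (1, n_t2d)):
            sel = agent_state == st
            np.add.at(arr, (agent_age[sel] - AGE_MIN, agent_g[sel], agent_q[sel]), 1.0)
        return StateVector(year, n_free * scale, n_t2d * scale)

    traj = PopulationTrajectory(states=[_occupancy(initial_state.year)])
    year = initial_state.year
    while year < horizon:
        p = scenario_probs.year_slice(year)
        ai = agent_age - AGE_MIN
        u = rng.random(agent_state.size)
        alive_free = agent_state == 0
        alive_t2d = agent_state == 1
        p_mf = np.nan_to_num(p["p_m_free"])[ai, agent_g, agent_q]
        p_in = np.nan_to_num(p["p_inc"])[ai, agent_g, agent_q]
        p_mt = np.nan_to_num(p["p_m_t2d"])[ai, agent_g, agent_q]
        dies_free = alive_free & (u < p_mf)
        becomes = alive_free & ~dies_free & (u < p_mf + p_in)
        dies_t2d = alive_t2d & (u < p_mt)
        agent_state[dies_free | dies_t2d] = 2
        agent_state[becomes] = 1
        agent_age = np.minimum(agent_age + 1, AGE_MAX)
        year += 1
        # entrants at age 30, disease-free, scaled to agent units
        ent = entrants.for_year(year) / scale
        ent_counts = _allocate(ent, int(round(ent.sum())))
        if ent_counts.sum() > 0:
            eg, eq = np.nonzero(ent_counts)
            reps = ent_counts[eg, eq]
            agent_age = np.concatenate([agent_age, np.full(reps.sum(), AGE_MIN)])
            agent_g = np.concatenate([agent_g, np.repeat(eg, reps)])
            agent_q = np.concatenate([agent_q, np.repeat(eq, reps)])
            agent_state = np.concatenate([agent_state, np.zeros(reps.sum(), dtype=int)])
        traj.states.append(_occupancy(year))
    return traj


# ----------------------------------------------------------------------
# prevalence reporting
# ----------------------------------------------------------------------
def initial_state_from_register(
    register: pd.DataFrame,
    ascertainment: pd.DataFrame,
    truth: pd.DataFrame | None,
    year: int,
    quintile_source: str = "register",
) -> StateVector:
    """Start-of-year occupancy at ``year`` from the synthetic register."""
    from .synth_register import assign_income_quintiles

    rows = register[register["year"] == year].copy()
    if rows.empty:
        raise ValueError(f"register has no rows for year {year}")
    rows["age"] = np.clip(rows["year"] - rows["birth_year"], AGE_MIN, AGE_MAX)
    if quintile_source == "truth":
        if truth is None:
            raise ValueError("quintile_source='truth' requires the truth frame")
        rows = rows.merge(truth[["person_id", "quintile"]], on="person_id")
    else:
        rows["quintile"] = assign_income_quintiles(rows).to_numpy()
    inc = rows["person_id"].map(ascertainment.set_index("person_id")["incidence_year"])
    has_t2d = (inc < rows["year"]).to_numpy()

    n_free = np.zeros(_SHAPE)
    n_t2d = np.zeros(_SHAPE)
    ai = rows["age"].to_numpy(int) - AGE_MIN
    gi = pd.Categorical(rows["gender"], categories=list(GENDERS)).codes
    qi = rows["quintile"].to_numpy(int) - 1
    np.add.at(n_free, (ai[~has_t2d], gi[~has_t2d], qi[~has_t2d]), 1.0)
    np.add.at(n_t2d, (ai[has_t2d], gi[has_t2d], qi[has_t2d]), 1.0)
    return StateVector(year, n_free, n_t2d)


def prevalence_table(traj: PopulationTrajectory, years=(2020, 2030, 2040)) -> pd.DataFrame:
    """Prevalent T2D counts by quintile for selected years, with changes.

    One row per income quintile plus an all-groups row and the gap between
    the most deprived and highest-income quintiles; columns give counts per
    year, pairwise differences against the first year and their % change
    (computed as (late - early) / early).
    """
    years = list(years)
    counts = {}
    for y in years:
        s = traj.state_at(y)
        counts[y] = s.n_t2d.sum(axis=(0, 1))  # per quintile
    rows = []
    labels = ["All"] + [f"Q{q}" for q in QUINTILES]
    for label in labels:
        rec = {"group": label}
        for y in years:
            c = counts[y].sum() if label == "All" else counts[y][int(label[1]) - 1]
            rec[f"n_{y}"] = float(c)
        for y in years[1:]:
            diff = rec[f"n_{y}"] - rec[f"n_{years[0]}"]
            rec[f"diff_{years[0]}_{y}"] = diff
            rec[f"pct_{years[0]}_{y}"] = 100.0 * diff / rec[f"n_{years[0]}"]
        rows.append(rec)
    gap = {"group": "Q5-Q1"}
    for y in years:
        q1, q5 = counts[y][0], counts[y][4]
        gap[f"n_{y}"] = float(q5 - q1)
        gap[f"gap_pct_{y}"] = 100.0 * (q5 - q1) / q1
    rows.append(gap)
    return pd.DataFrame(rows)
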