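"""Period life expectancy at 65 partitioned by T2D state.

For a calendar year's transition schedule, a synthetic period cohort is
started at age 65 with that year's projected prevalence mix (share free /
share with T2D) and pushed through the illness-death chain with the same
update rule as the projection engine.  Person-years accrue by state with
the standard abridged-life-table convention ``a_x = 0.5``: deaths earn a
half year in the year of death, and the year of T2D onset is split
half-and-half between states.  Total life expectancy at 65 (TLE65) then
partitions exactly into LE-with-T2D and LE-without-T2D.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import PopulationTrajectory
from .probset import AGE_MAX, AGE_MIN, GENDERS, QUINTILES, TransitionProbabilitySet

START_AGE = 65


def period_state_expectancies_at_65(
    probs: TransitionProbabilitySet,
    year: int,
    gender: str,
    quintile: int,
    state_mix: tuple[float, float],
) -> tuple[float, float, float]:
    """(TLE65, LE_without, LE_with) for one stratum and calendar year.

    ``state_mix`` is (share disease-free, share with T2D) at exact age 65;
    the shares must sum to 1.  The chain uses the single calendar year's
    schedule at every age (period, not cohort, life expectancy).
    """
    share_free, share_t2d = state_mix
    if not np.isclose(share_free + share_t2d, 1.0):
        raise ValueError("state mix must sum to 1")
    gi = list(GENDERS).index(gender)
    qi = int(quintile) - 1
    sl = probs.year_slice(year)
    p_inc = sl["p_inc"][:, gi, qi]
    p_mf = sl["p_m_free"][:, gi, qi]
    p_mt = sl["p_m_t2d"][:, gi, qi]
    a0 = START_AGE - AGE_MIN
    if np.isnan(p_inc[a0:]).any() or np.isnan(p_mf[a0:]).any() or np.isnan(p_mt[a0:]).any():
        raise ValueError(f"missing probabilities for ages {START_AGE}-{AGE_MAX} in {year}")

    l_free, l_t2d = float(share_free), float(share_t2d)
    py_free = py_t2d = 0.0
    for a in range(a0, AGE_MAX - AGE_MIN + 1):
        d_free = l_free * p_mf[a]
        inc = l_free * p_inc[a]
        d_t2d = l_t2d * p_mt[a]
        # full year for survivors, half for deaths; onset year split half/half
        py_free += (l_free - d_free - inc) + 0.5 * d_free + 0.5 * inc
        py_t2d += (l_t2d - d_t2d) + 0.5 * d_t2d + 0.5 * inc
        l_free = l_free - d_free - inc
        l_t2d = l_t2d - d_t2d + inc
    # terminal age has mortality 1, so the chain is exhausted here
    tle = py_free + py_t2d
    return tle, py_free, py_t2d


def state_mix_at_65(traj: PopulationTrajectory, year: int, gender: str, quintile: int) -> tuple[float, float]:
    """Projected (share free, share T2D) at age 65 in a stratum-year."""
    s = traj.state_at(year)
    gi = list(GENDERS).index(gender)
    qi = int(quintile) - 1
    a = START_AGE - AGE_MIN
    nf, nt = s.n_free[a, gi, qi], s.n_t2d[a, gi, qi]
    tot = nf + nt
    if tot <= 0:
        return 1.0, 0.0
    return nf / tot, nt / tot


def health_expectancy_table(
    traj: PopulationTrajectory,
    scenario_probs: TransitionProbabilitySet,
    years=(2020, 2040),
) -> pd.DataFrame:
    """TLE65 and its partition per gender x quintile x year.

    Columns: ``tle65, le_without, le_with, prop_without`` plus, per gender
    and pair of years, derived change rows; Q5-Q1 gap rows come from
    :func:`inequality_summary`.
    """
    rows = []
    for g in GENDERS:
        for q in QUINTILES:
            for y in years:
                mix = state_mix_at_65(traj, y, g, q)
                tle, le_wo, le_w = period_state_expectancies_at_65(
                    scenario_probs, y, g, q, mix
                )
                rows.append(
                    {
                        "gender": g,
                        "quintile": q,
                        "year": y,
                        "tle65": tle,
                        "le_without": le_wo,
                        "le_with": le_w,
                        "prop_without": le_wo / tle if tle > 0 else np.nan,
                    }
                )
    df = pd.DataFrame(rows)
    bad = np.abs(df["le_with"] + df["le_without"] - df["tle65"]) > 1e-9
    if bad.any():
        raise AssertionError("LE partition identity violated")
    return df


def inequality_summary(het: pd.DataFrame) -> pd.DataFrame:
    """Q5 - Q1 gaps (absolute and % of the Q1 value) per gender and year."""
    rows = []
    for (g, y), sub in het.groupby(["gender", "year"]):
        q1 = sub[sub["quintile"] == 1]
        q5 = sub[sub["quintile"] == 5]
        if q1.empty or q5.empty:
            raise ValueError("both Q1 and Q5 must be present")
        rec = {"gender": g, "year": y}
        for col in ("tle65", "le_without", "le_with", "prop_without"):
            a, b = float(q1[col].iloc[0]), float(q5[col].iloc[0])
            rec[f"gap_{col}"] = b - a
            rec[f"gap_pct_{col}"] = 100.0 * (b - a) / a if a != 0 else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def change_summary(het: pd.DataFrame, year_from: int, year_to: int) -> pd.DataFrame:
    """Change between two years per gender x quintile, with % change."""
    rows = []
    for (g, q), sub in het.groupby(["gender", "quintile"]):
        early = sub[sub["year"] == year_from]
        late = sub[sub["year"] == year_to]
        if early.empty or late.empty:
            continue
        rec = {"gender": g, "quintile": q}
        for col in ("tle65", "le_without", "le_with", "prop_without"):
            a, b = float(early[col].iloc[0]), float(late[col].iloc[0])
            rec[f"change_{col}"] = b - a
            rec[f"change_pct_{col}"] = 100.0 * (b - a) / a if a != 0 else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
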