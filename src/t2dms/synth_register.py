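"""Synthetic medication-reimbursement register with planted ground truth.

The real analysis runs on licensed population-register data (all residents
aged 30+, linked to the medication reimbursement register, income records
and mortality follow-up).  That register cannot be redistributed, so this
module generates a register-shaped stand-in whose disease dynamics follow a
known :class:`GroundTruthSchedule`.  Because the truth is known, estimation
and projection can be tested for parameter recovery rather than eyeballed.

The module also implements the analysis-side operations that in the real
study run against the register itself:

* OECD-modified income equivalisation and annual quintile assignment within
  5-year age strata (Q1 = highest income, Q5 = most deprived);
* pharmacologically-treated T2D case ascertainment from purchase and
  special-reimbursement histories (five criteria);
* aggregation of person-years into occurrence/exposure counts by
  age x gender x quintile x calendar year.

State-timing convention (fixed throughout the package): state is evaluated
at the start of each calendar year.  A person whose first qualifying
register entry falls in year ``t`` transitions at the end of ``t``: during
``t`` they count as at-risk in the disease-free state, and they occupy the
T2D state from ``t + 1`` onward.  Events are attributed to the
start-of-year state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RegisterConfig, ScheduleConfig
from .probset import AGE_MAX, AGE_MIN, GENDERS, QUINTILES, TransitionProbabilitySet

# ATC classes used by the ascertainment criteria
SECRETAGOGUE_PREFIXES = ("A10BB", "A10BH", "A10BX02", "A10BX03", "A10BX04")
ANY_A10B_PREFIX = "A10B"
INSULIN_PREFIX = "A10A"

# concrete codes written by the generator, one per pathway
_CODE_METFORMIN = "A10BA02"
_CODE_SULFONYLUREA = "A10BB01"
_CODE_INSULIN = "A10AB01"

GRANT_T2D = "T2D_specific"
GRANT_UNSPEC = "unspecified_diabetes"

_NO_EVENT = 10**9  # sentinel year meaning "never"


# ----------------------------------------------------------------------
# person-level domain types
# ----------------------------------------------------------------------
@dataclass
class ReimbursementGrant:
    year: int
    diagnosis: str  # GRANT_T2D or GRANT_UNSPEC
    age_at_grant: int


@dataclass
class PersonYear:
    year: int
    household_income: float
    n_adults: int
    n_children: int
    purchases: frozenset = frozenset()
    grants: tuple = ()
    died: bool = False


@dataclass
class PersonRecord:
    person_id: int
    gender: str
    birth_year: int
    followup: list = field(default_factory=list)


@dataclass
class AscertainmentResult:
    is_t2d: bool
    incidence_year: int | None = None
    triggering_criterion: int | None = None


# ----------------------------------------------------------------------
# OECD-modified equivalence scale
# ----------------------------------------------------------------------
def oecd_modified_weight(n_adults: int, n_children: int) -> float:
    """Household weight: 1.0 first adult, 0.5 per further adult, 0.3 per child."""
    if n_adults < 1:
        raise ValueError("household must contain at least one adult")
    if n_children < 0:
        raise ValueError("n_children must be non-negative")
    return 1.0 + 0.5 * (n_adults - 1) + 0.3 * n_children


def equivalize_income(household_income, n_adults, n_children):
    """Divide household income by the OECD-modified scale weight.

    Accepts scalars or aligned arrays; raises on households with no adult.
    """
    n_adults = np.asarray(n_adults)
    n_children = np.asarray(n_children)
    if (n_adults < 1).any():
        raise ValueError("household must contain at least one adult")
    if (n_children < 0).any():
        raise ValueError("n_children must be non-negative")
    weight = 1.0 + 0.5 * (n_adults - 1) + 0.3 * n_children
    out = np.asarray(household_income, dtype=float) / weight
    return float(out) if out.ndim == 0 else out


# ----------------------------------------------------------------------
# income quintiles within 5-year age strata
# ----------------------------------------------------------------------
def age_stratum(age) -> np.ndarray:
    """5-year stratum label: 30-34, 35-39, ..., 95-99, 100+ (coded 100)."""
    a = np.clip(np.asarray(age, dtype=int), AGE_MIN, AGE_MAX)
    return np.minimum((a - AGE_MIN) // 5 * 5 + AGE_MIN, AGE_MAX)


def assign_income_quintiles(df: pd.DataFrame, year: int | None = None) -> pd.Series:
    """Quintile per row from equivalised income ranked within age strata.

    ``df`` needs columns ``person_id, year, age, income, n_adults,
    n_children`` (``income`` is household income before equivalisation).
    Ranking is within (year, 5-year age stratum): the highest equivalised
    incomes go to Q1, the lowest to Q5.  Ties break by ascending person_id
    so the assignment is deterministic.  Group sizes within a stratum
    differ by at most one.
    """
    sub = df if year is None else df[df["year"] == year]
    if sub.empty:
        warnings.warn("no rows to assign quintiles to", stacklevel=2)
        return pd.Series(dtype=int)
    eq = equivalize_income(
        sub["income"].to_numpy(), sub["n_adults"].to_numpy(), sub["n_children"].to_numpy()
    )
    work = pd.DataFrame(
        {
            "stratum": age_stratum(sub["age"].to_numpy()),
            "year": sub["year"].to_numpy(),
            "eq": eq,
            "pid": sub["person_id"].to_numpy(),
        },
        index=sub.index,
    )
    order = np.lexsort((work["pid"].to_numpy(), -work["eq"].to_numpy()))
    work = work.iloc[order]
    grp = work.groupby(["year", "stratum"], sort=False)
    rank = grp.cumcount().to_numpy()
    size = grp["eq"].transform("size").to_numpy()
    quint = (rank * 5 // size + 1).astype(int)  # descending income -> Q1 first
    return pd.Series(quint, index=work.index, name="quintile").reindex(sub.index)


# ----------------------------------------------------------------------
# case ascertainment (five criteria)
# ----------------------------------------------------------------------
def _is_secretagogue(code: str) -> bool:
    return code.startswith(SECRETAGOGUE_PREFIXES)


def ascertain_t2d(person: PersonRecord) -> AscertainmentResult:
    """Classify one person as pharmacologically treated T2D.

    Criteria (any one suffices):

    1. special reimbursement granted with a T2D diagnosis;
    2. any purchase of insulin-secretion stimulating medication
       (A10BB, A10BH, A10BX02/03/04);
    3. more calendar years with any blood-glucose-lowering (A10B) purchase
       than years with insulin (A10A) purchases;
    4. equally many A10B and insulin years, and age at first purchase >= 40;
    5. special reimbursement with unspecified diabetes diagnosis at age >= 40.

    The incidence year is the earliest register entry (purchase or grant)
    for an ascertained case.  The reported criterion is the smallest
    qualifying number.
    """
    years_a10b: set[int] = set()
    years_insulin: set[int] = set()
    first_purchase_age: int | None = None
    crit1 = crit2 = crit5 = False
    entry_years: list[int] = []
    for py in person.followup:
        has_purchase = False
        for code in py.purchases:
            has_purchase = True
            if code.startswith(ANY_A10B_PREFIX):
                years_a10b.add(py.year)
                if _is_secretagogue(code):
                    crit2 = True
            if code.startswith(INSULIN_PREFIX):
                years_insulin.add(py.year)
        if has_purchase:
            entry_years.append(py.year)
            age = py.year - person.birth_year
            if first_purchase_age is None:
                first_purchase_age = age
        for grant in py.grants:
            entry_years.append(grant.year)
            if grant.diagnosis == GRANT_T2D:
                crit1 = True
            elif grant.diagnosis == GRANT_UNSPEC and grant.age_at_grant >= 40:
                crit5 = True
    crit3 = len(years_a10b) > len(years_insulin)
    crit4 = (
        len(years_a10b) == len(years_insulin)
        and len(years_a10b) >= 1
        and first_purchase_age is not None
        and first_purchase_age >= 40
    )
    for number, hit in enumerate((crit1, crit2, crit3, crit4, crit5), start=1):
        if hit:
            return AscertainmentResult(True, min(entry_years), number)
    return AscertainmentResult(False)


def ascertain_register(register: pd.DataFrame) -> pd.DataFrame:
    """Vectorised ascertainment over a long-format register.

    Returns one row per person: ``person_id, is_t2d, incidence_year,
    criterion`` (NaN where absent).  Mirrors :func:`ascertain_t2d` exactly.
    """
    codes = register["atc_codes"].fillna("")
    has_any = codes.str.len() > 0
    # prefix-anchored at each ';'-separated code
    has_a10b = codes.str.contains(r"(?:^|;)A10B")
    has_insulin = codes.str.contains(r"(?:^|;)A10A")
    has_secret = codes.str.contains(
        r"(?:^|;)(?:" + "|".join(SECRETAGOGUE_PREFIXES) + ")"
    )
    grant = register["grant_type"].fillna("")
    age = register["year"] - register["birth_year"]

    tab = pd.DataFrame(
        {
            "person_id": register["person_id"],
            "year": register["year"],
            "entry": (has_any | (grant != "")),
            "a10b_year": has_a10b,
            "ins_year": has_insulin,
            "secret": has_secret,
            "grant_t2d": grant == GRANT_T2D,
            "grant_unspec40": (grant == GRANT_UNSPEC) & (age >= 40),
            "purchase_age": np.where(has_any, age, np.inf),
            "entry_year": np.where(has_any | (grant != ""), register["year"], _NO_EVENT),
        }
    )
    g = tab.groupby("person_id", sort=True)
    per = g.agg(
        n_a10b_years=("a10b_year", "sum"),
        n_ins_years=("ins_year", "sum"),
        crit2=("secret", "any"),
        crit1=("grant_t2d", "any"),
        crit5=("grant_unspec40", "any"),
        first_purchase_age=("purchase_age", "min"),
        first_entry=("entry_year", "min"),
    )
    crit3 = per["n_a10b_years"] > per["n_ins_years"]
    crit4 = (
        (per["n_a10b_years"] == per["n_ins_years"])
        & (per["n_a10b_years"] >= 1)
        & (per["first_purchase_age"] >= 40)
        & np.isfinite(per["first_purchase_age"])
    )
    crits = np.column_stack(
        [per["crit1"], per["crit2"], crit3, crit4, per["crit5"]]
    ).astype(bool)
    is_t2d = crits.any(axis=1)
    criterion = np.where(is_t2d, crits.argmax(axis=1) + 1, np.nan)
    out = pd.DataFrame(
        {
            "person_id": per.index,
            "is_t2d": is_t2d,
            "incidence_year": np.where(is_t2d, per["first_entry"], np.nan),
            "criterion": criterion,
        }
    ).reset_index(drop=True)
    return out


# ----------------------------------------------------------------------
# ground-truth transition schedule
# ----------------------------------------------------------------------
@dataclass
class GroundTruthSchedule:
    """Parametric transition schedule the generator simulates from.

    Provides the exact probability surfaces for any span of years, so tests
    can compare estimates and projections against analytic truth.
    """

    params: ScheduleConfig = field(default_factory=ScheduleConfig)

    def __post_init__(self) -> None:
        p = self.params
        for name in ("inc_peak_m", "inc_peak_f", "mort30_m", "mort30_f"):
            v = getattr(p, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if p.bump_multiplier < 0 or p.incidence_scale < 0:
            raise ValueError("multipliers must be non-negative")

    def _year_multiplier_inc(self, years: np.ndarray) -> np.ndarray:
        p = self.params
        mult = np.where(
            years <= p.bump_start - 1,
            np.exp(p.inc_pre_trend * (years - (p.bump_start - 1))),
            1.0,
        )
        in_bump = (years >= p.bump_start) & (years <= p.bump_end)
        mult = np.where(in_bump, p.bump_multiplier, mult)
        post = years >= p.decline_start
        mult = np.where(post, np.exp(-p.inc_decline_rate * (years - p.decline_start)), mult)
        return mult

    def probability_set(self, years) -> TransitionProbabilitySet:
        """Exact schedule on a dense (age, gender, quintile, year) grid."""
        p = self.params
        years = np.asarray(list(years), dtype=int)
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
        a = ages[:, None, None, None].astype(float)
        g = np.arange(2)[None, :, None, None]  # 0 = M, 1 = F
        q = np.arange(1, 6)[None, None, :, None].astype(float)
        y = years[None, None, None, :].astype(float)

        peak = np.where(g == 0, p.inc_peak_m, p.inc_peak_f)
        # deprived quintiles develop T2D at earlier ages as well as at higher rates
        peak_age = p.inc_peak_age - p.inc_peak_age_gradient * (q - 3)
        age_shape = np.exp(-(((a - peak_age) / p.inc_age_width) ** 2))
        inc = (
            p.incidence_scale
            * peak
            * age_shape
            * np.exp(p.inc_quintile_log_gradient * (q - 3))
            * self._year_multiplier_inc(y)
        )

        mort30 = np.where(g == 0, p.mort30_m, p.mort30_f)
        # income differences in mortality attenuate toward the oldest ages
        if p.mort_grad_fade_age:
            fade = np.clip((p.mort_grad_fade_age - a) / (p.mort_grad_fade_age - AGE_MIN), 0.0, 1.0)
        else:
            fade = 1.0
        m_free = (
            mort30
            * np.exp(p.gompertz_slope * (a - AGE_MIN))
            * np.exp(p.mort_quintile_log_gradient * (q - 3) * fade)
            * np.exp(-p.mort_decline_rate * (y - p.mort_ref_year))
        )
        m_free = np.clip(m_free, 0.0, 0.7)
        excess = 1.0 + p.t2d_excess_at30 * np.exp(-(a - AGE_MIN) / p.t2d_excess_age_tau)
        m_t2d = np.clip(m_free * excess, 0.0, 0.95)
        inc = np.clip(inc, 0.0, 1.0 - m_free)

        out = TransitionProbabilitySet(
            years=years, p_inc=inc, p_m_free=m_free, p_m_t2d=m_t2d
        )
        out.enforce_terminal_age()
        out.validate()
        return out

    def initial_prevalence(self, ages, gender_idx, quintile, scale: float = 1.0) -> np.ndarray:
        """Plausible T2D prevalence at cohort entry (drives the 1995 state)."""
        ages = np.asarray(ages, dtype=float)
        base = 0.26 / (1.0 + np.exp(-(ages - 72.0) / 9.0))
        gmult = np.where(np.asarray(gender_idx) == 0, 1.10, 0.95)
        qmult = np.exp(0.08 * (np.asarray(quintile) - 3))
        return np.clip(scale * base * gmult * qmult, 0.0, 0.6)


# ----------------------------------------------------------------------
# register generation
# ----------------------------------------------------------------------
def _initial_age_weights(ages: np.ndarray) -> np.ndarray:
    """Start-year age pyramid: declining with age plus a baby-boom bulge.

    The bulge around ages 45-50 stands in for the large post-WWII birth
    cohorts, whose aging into the high-prevalence ages drives much of the
    projected growth in T2D counts.
    """
    w = np.exp(-np.maximum(0.0, ages - 50.0) / 14.0) + 0.55 * np.exp(
        -(((ages - 47.0) / 5.0) ** 2)
    )
    return w / w.sum()


def generate_register(
    cfg: RegisterConfig,
    schedule: GroundTruthSchedule,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a register and return ``(register, truth)``.

    ``register`` is the long person-year table (one row per person per
    calendar year alive at the start of the year) with the columns the real
    register would expose: ``person_id, year, gender, birth_year, income,
    n_adults, n_children, atc_codes, grant_type, died``.

    ``truth`` is one row per person with the simulated ground truth
    (``quintile, incidence_year, death_year, pathway, prevalent_at_entry``),
    never visible to the estimation code except in tests.

    The same draw order is used regardless of parameter values, so the
    output is byte-identical for a fixed seed and config.
    """
    rng = np.random.default_rng(seed)
    years = np.arange(cfg.start_year, cfg.end_year + 1)
    probs = schedule.probability_set(years)

    # --- persons: initial cohort + one entrant cohort per later year
    n0 = int(cfg.n_persons)
    n_entrants_per_year = int(round(cfg.n_persons * cfg.entrant_rate))
    entry_chunks = [np.full(n0, cfg.start_year)]
    age_at_entry = [
        rng.choice(
            np.arange(AGE_MIN, AGE_MAX + 1),
            size=n0,
            p=_initial_age_weights(np.arange(AGE_MIN, AGE_MAX + 1, dtype=float)),
        )
    ]
    for y in years[1:]:
        entry_chunks.append(np.full(n_entrants_per_year, y))
        age_at_entry.append(np.full(n_entrants_per_year, AGE_MIN))
    entry_year = np.concatenate(entry_chunks)
    entry_age = np.concatenate(age_at_entry)
    n = entry_year.size

    person_id = np.arange(n)
    birth_year = entry_year - entry_age
    gender_idx = rng.integers(0, 2, size=n)  # 0 = M, 1 = F
    quintile = rng.integers(1, 6, size=n)
    # income percentile fixed within the person's quintile band (Q1 = top)
    pctl = rng.uniform((5 - quintile) / 5.0, (6 - quintile) / 5.0)
    n_adults = np.where(rng.random(n) < 0.30, 1, 2)
    child_u = rng.random(n)
    n_children = np.select([child_u < 0.55, child_u < 0.85], [0, 1], default=2)

    # --- disease state at entry
    prev_p = schedule.initial_prevalence(
        entry_age, gender_idx, quintile, cfg.initial_prevalence_scale
    )
    prev_p = np.where(entry_age == AGE_MIN, 0.0, prev_p)  # entrants are disease-free
    prevalent = rng.random(n) < prev_p

    # --- simulate transitions year by year (state at start of year)
    incidence_year = np.where(prevalent, entry_year - 1, _NO_EVENT)
    death_year = np.full(n, _NO_EVENT)
    for t, y in enumerate(years):
        alive = (entry_year <= y) & (death_year == _NO_EVENT)
        age = np.clip(y - birth_year, AGE_MIN, AGE_MAX)
        ai = age - AGE_MIN
        gi = gender_idx
        qi = quintile - 1
        u = rng.random(n)
        p_inc = probs.p_inc[ai, gi, qi, t]
        p_mf = probs.p_m_free[ai, gi, qi, t]
        p_mt = probs.p_m_t2d[ai, gi, qi, t]
        has_t2d = incidence_year < y
        free = alive & ~has_t2d
        dies_free = free & (u < p_mf)
        becomes_inc = free & ~dies_free & (u < p_mf + p_inc)
        dies_t2d = alive & has_t2d & (u < p_mt)
        death_year[dies_free | dies_t2d] = y
        incidence_year[becomes_inc] = y

    # --- ascertainment pathway per true case
    ever_t2d = incidence_year < _NO_EVENT
    shares = np.asarray(cfg.pathway_shares, dtype=float)
    shares = shares / shares.sum()
    pathway = np.where(ever_t2d, rng.choice(np.arange(1, 6), size=n, p=shares), 0)
    # first register entry: purchases only exist inside the observation window
    onset_visible = np.maximum(np.where(prevalent, entry_year, incidence_year), cfg.start_year)
    onset_age = onset_visible - birth_year
    needs40 = (pathway == 4) | (pathway == 5)
    pathway = np.where(ever_t2d & needs40 & (onset_age < 40), 3, pathway)

    decoy = ~ever_t2d & (rng.random(n) < cfg.decoy_insulin_fraction)
    decoy_start = np.maximum(entry_year, cfg.start_year)

    # --- expand to person-years
    last_year = np.minimum(np.where(death_year == _NO_EVENT, cfg.end_year, death_year), cfg.end_year)
    n_years = last_year - np.maximum(entry_year, cfg.start_year) + 1
    keep = n_years > 0
    counts = n_years[keep]
    idx = np.repeat(np.flatnonzero(keep), counts)
    cum = np.concatenate([[0], np.cumsum(counts)])
    pos = np.arange(cum[-1]) - np.repeat(cum[:-1], counts)
    row_year = np.maximum(entry_year, cfg.start_year)[idx] + pos

    eq_base = stats.lognorm.ppf(pctl, s=cfg.income_sigma, scale=cfg.income_median)
    weight = 1.0 + 0.5 * (n_adults - 1) + 0.3 * n_children
    row_income = (
        eq_base[idx] * weight[idx] * (1.0 + cfg.income_growth) ** (row_year - cfg.start_year)
    )

    on_treatment = ever_t2d[idx] & (row_year >= onset_visible[idx])
    path_row = pathway[idx]
    codes = np.full(row_year.size, "", dtype=object)
    codes[on_treatment & (path_row == 1)] = _CODE_METFORMIN
    codes[on_treatment & (path_row == 2)] = _CODE_SULFONYLUREA
    codes[on_treatment & (path_row == 3)] = _CODE_METFORMIN
    codes[on_treatment & (path_row == 4)] = _CODE_METFORMIN + ";" + _CODE_INSULIN
    codes[on_treatment & (path_row == 5)] = _CODE_INSULIN
    is_decoy_row = decoy[idx] & (row_year >= decoy_start[idx])
    codes[is_decoy_row] = _CODE_INSULIN

    grants = np.full(row_year.size, "", dtype=object)
    at_onset = on_treatment & (row_year == onset_visible[idx])
    grants[at_onset & (path_row == 1)] = GRANT_T2D
    grants[at_onset & (path_row == 5)] = GRANT_UNSPEC

    register = pd.DataFrame(
        {
            "person_id": person_id[idx],
            "year": row_year,
            "gender": np.array(GENDERS)[gender_idx[idx]],
            "birth_year": birth_year[idx],
            "income": row_income,
            "n_adults": n_adults[idx],
            "n_children": n_children[idx],
            "atc_codes": codes,
            "grant_type": grants,
            "died": death_year[idx] == row_year,
        }
    )

    truth = pd.DataFrame(
        {
            "person_id": person_id,
            "gender": np.array(GENDERS)[gender_idx],
            "birth_year": birth_year,
            "entry_year": entry_year,
            "quintile": quintile,
            "prevalent_at_entry": prevalent,
            "incidence_year": np.where(ever_t2d, incidence_year, np.nan),
            "death_year": np.where(death_year == _NO_EVENT, np.nan, death_year),
            "pathway": pathway,
            "decoy": decoy,
        }
    )
    return register, truth


def register_to_person_records(register: pd.DataFrame) -> list[PersonRecord]:
    """Inflate the long register into per-person records (small inputs only)."""
    records = []
    for pid, sub in register.groupby("person_id", sort=True):
        sub = sub.sort_values("year")
        first = sub.iloc[0]
        person = PersonRecord(
            person_id=int(pid), gender=str(first["gender"]), birth_year=int(first["birth_year"])
        )
        for _, row in sub.iterrows():
            codes = frozenset(c for c in str(row["atc_codes"]).split(";") if c)
            grants = ()
            if row["grant_type"]:
                grants = (
                    ReimbursementGrant(
                        year=int(row["year"]),
                        diagnosis=str(row["grant_type"]),
                        age_at_grant=int(row["year"] - row["birth_year"]),
                    ),
                )
            person.followup.append(
                PersonYear(
                    year=int(row["year"]),
                    household_income=float(row["income"]),
                    n_adults=int(row["n_adults"]),
                    n_children=int(row["n_children"]),
                    purchases=codes,
                    grants=grants,
                    died=bool(row["died"]),
                )
            )
        records.append(person)
    return records


# ----------------------------------------------------------------------
# occurrence/exposure aggregation
# ----------------------------------------------------------------------
COUNT_COLUMNS = ("n_free", "n_incident", "n_death_free", "n_t2d", "n_death_t2d")


def aggregate_counts(
    register: pd.DataFrame,
    ascertainment: pd.DataFrame,
    quintile_source: str = "register",
    truth: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tally person-years into occurrence/exposure counts.

    Each register row is one person-year; the state occupied at the start
    of the year is disease-free unless the ascertained incidence year is
    strictly earlier.  Events within the year (incidence = first register
    entry; death) are attributed to the start-of-year state, matching the
    projection engine's update rule.

    ``quintile_source`` is either ``"register"`` (annual quintiles re-derived
    from income, as in the real analysis) or ``"truth"`` (the generator's
    fixed quintile; requires ``truth``).

    Returns a tidy frame with columns ``age, gender, quintile, year`` plus
    ``n_free, n_incident, n_death_free, n_t2d, n_death_t2d``.
    """
    df = register[["person_id", "year", "gender", "birth_year", "died"]].copy()
    df["age"] = np.clip(df["year"] - df["birth_year"], AGE_MIN, AGE_MAX)
    if quintile_source == "truth":
        if truth is None:
            raise ValueError("quintile_source='truth' requires the truth frame")
        df = df.merge(truth[["person_id", "quintile"]], on="person_id", how="left")
    elif quintile_source == "register":
        cols = register[["person_id", "year", "income", "n_adults", "n_children"]].copy()
        cols["age"] = df["age"].to_numpy()
        df["quintile"] = assign_income_quintiles(cols).to_numpy()
    else:
        raise ValueError(f"unknown quintile_source {quintile_source!r}")

    asc = ascertainment.set_index("person_id")["incidence_year"]
    inc_year = df["person_id"].map(asc).to_numpy(dtype=float)
    year = df["year"].to_numpy()
    has_t2d = inc_year < year  # start-of-year state
    died = df["died"].to_numpy(dtype=bool)
    # death in the incidence year is a free-state death (the within-year
    # ordering puts death before the T2D transition, as in the engine)
    incident = (inc_year == year) & ~died
    if (incident & has_t2d).any():
        raise ValueError("person-year in both states: inconsistent incidence year")

    out = pd.DataFrame(
        {
            "age": df["age"].to_numpy(),
            "gender": df["gender"].to_numpy(),
            "quintile": df["quintile"].to_numpy(),
            "year": year,
            "n_free": (~has_t2d).astype(int),
            "n_incident": incident.astype(int),
            "n_death_free": (died & ~has_t2d).astype(int),
            "n_t2d": has_t2d.astype(int),
            "n_death_t2d": (died & has_t2d).astype(int),
        }
    )
    counts = (
        out.groupby(["age", "gender", "quintile", "year"], sort=True, observed=True)
        .sum()
        .reset_index()
    )
    validate_counts(counts)
    return counts


def validate_counts(counts: pd.DataFrame) -> None:
    for col in COUNT_COLUMNS:
        if (counts[col] < 0).any():
            raise ValueError(f"negative count in {col}")
    if (counts["n_incident"] > counts["n_free"]).any():
        raise ValueError("incident events exceed at-risk count")
    if (counts["n_death_free"] > counts["n_free"]).any():
        raise ValueError("free-state deaths exceed at-risk count")
    if (counts["n_death_t2d"] > counts["n_t2d"]).any():
        raise ValueError("T2D deaths exceed at-risk count")
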