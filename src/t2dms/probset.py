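"""Annual transition probabilities for the illness-death model.

The three-state model (free of T2D -> T2D -> dead, free -> dead, no
recovery) is driven by one-year transition probabilities specific to age,
gender, income quintile and calendar year:

* ``p_inc``    -- P(free -> T2D) within the year,
* ``p_m_free`` -- P(free -> dead),
* ``p_m_t2d``  -- P(T2D -> dead).

:class:`TransitionProbabilitySet` stores the three probability surfaces as
dense ``(age, gender, quintile, year)`` arrays with NaN marking cells that
were never observed.  Optional exposure arrays (person-years at risk in each
state) ride along so that smoothing and trend fitting can weight by the
amount of information behind each cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENDERS = ("M", "F")
QUINTILES = (1, 2, 3, 4, 5)  # Q1 = highest income, Q5 = most deprived
AGE_MIN = 30
AGE_MAX = 100  # open-ended terminal age; mortality forced to 1 here

_PROB_COLUMNS = ("p_inc", "p_m_free", "p_m_t2d")


@dataclass
class TransitionProbabilitySet:
    """Dense container of annual transition probabilities.

    Parameters
    ----------
    years
        Consecutive calendar years covered.
    p_inc, p_m_free, p_m_t2d
        Arrays of shape ``(n_ages, 2, 5, n_years)`` with axes
        (age 30..100, gender M/F, quintile Q1..Q5, year).
    exposure_free, exposure_t2d
        Optional person-years at risk behind each cell, same shape.
    """

    years: np.ndarray
    p_inc: np.ndarray
    p_m_free: np.ndarray
    p_m_t2d: np.ndarray
    exposure_free: np.ndarray | None = None
    exposure_t2d: np.ndarray | None = None
    ages: np.ndarray = field(default_factory=lambda: np.arange(AGE_MIN, AGE_MAX + 1))

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.ages = np.asarray(self.ages, dtype=int)
        shape = (len(self.ages), len(GENDERS), len(QUINTILES), len(self.years))
        for name in _PROB_COLUMNS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    @classmethod
    def empty(cls, years) -> "TransitionProbabilitySet":
        years = np.asarray(years, dtype=int)
        shape = (AGE_MAX - AGE_MIN + 1, len(GENDERS), len(QUINTILES), len(years))
        return cls(
            years=years,
            p_inc=np.full(shape, np.nan),
            p_m_free=np.full(shape, np.nan),
            p_m_t2d=np.full(shape, np.nan),
        )

    def copy(self) -> "TransitionProbabilitySet":
        return TransitionProbabilitySet(
            years=self.years.copy(),
            p_inc=self.p_inc.copy(),
            p_m_free=self.p_m_free.copy(),
            p_m_t2d=self.p_m_t2d.copy(),
            exposure_free=None if self.exposure_free is None else self.exposure_free.copy(),
            exposure_t2d=None if self.exposure_t2d is None else self.exposure_t2d.copy(),
            ages=self.ages.copy(),
        )

    # ------------------------------------------------------------------
    # indexing
    # ------------------------------------------------------------------
    def year_index(self, year: int) -> int:
        idx = np.searchsorted(self.years, year)
        if idx >= len(self.years) or self.years[idx] != year:
            raise KeyError(f"year {year} not in probability set ({self.years[0]}..{self.years[-1]})")
        return int(idx)

    def year_slice(self, year: int) -> dict[str, np.ndarray]:
        """Return the three ``(age, gender, quintile)`` slabs for one year."""
        t = self.year_index(year)
        return {
            "p_inc": self.p_inc[..., t],
            "p_m_free": self.p_m_free[..., t],
            "p_m_t2d": self.p_m_t2d[..., t],
        }

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self, require_complete: bool = False) -> None:
        """Check probability ranges and the joint constraint p_inc + p_mF <= 1."""
        for name in _PROB_COLUMNS:
            arr = getattr(self, name)
            finite = arr[np.isfinite(arr)]
            if finite.size and ((finite < 0).any() or (finite > 1).any()):
                raise ValueError(f"{name} has values outside [0, 1]")
            if require_complete and not np.isfinite(arr).all():
                raise ValueError(f"{name} has missing cells")
        s = self.p_inc + self.p_m_free
        bad = np.isfinite(s) & (s > 1.0 + 1e-12)
        if bad.any():
            raise ValueError("p_inc + p_m_free exceeds 1 in some cells")

    def enforce_terminal_age(self) -> None:
        """Close the life table: certain death and no incidence at the top age."""
        self.p_m_free[-1, ...] = 1.0
        self.p_m_t2d[-1, ...] = 1.0
        self.p_inc[-1, ...] = 0.0

    # ------------------------------------------------------------------
    # tidy-frame / CSV round trip (lossless at 12 significant digits)
    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        a, g, q, y = np.meshgrid(
            self.ages, np.arange(2), np.arange(5), self.years, indexing="ij"
        )
        df = pd.DataFrame(
            {
                "age": a.ravel(),
                "gender": np.array(GENDERS)[g.ravel()],
                "quintile": np.array(QUINTILES)[q.ravel()],
                "year": y.ravel(),
                "p_inc": self.p_inc.ravel(),
                "p_m_free": self.p_m_free.ravel(),
                "p_m_t2d": self.p_m_t2d.ravel(),
            }
        )
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TransitionProbabilitySet":
        years = np.sort(df["year"].unique())
        out = cls.empty(years)
        gi = pd.Categorical(df["gender"], categories=list(GENDERS)).codes
        qi = df["quintile"].to_numpy(dtype=int) - 1
        ai = df["age"].to_numpy(dtype=int) - AGE_MIN
        ti = np.searchsorted(years, df["year"].to_numpy())
        if (gi < 0).any():
            raise ValueError("gender must be 'M' or 'F'")
        if (ai < 0).any() or (ai > AGE_MAX - AGE_MIN).any():
            raise ValueError(f"ages must lie in [{AGE_MIN}, {AGE_MAX}]")
        for name in _PROB_COLUMNS:
            getattr(out, name)[ai, gi, qi, ti] = df[name].to_numpy(dtype=float)
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "TransitionProbabilitySet":
        return cls.from_frame(pd.read_csv(path))

    def isclose(self, other: "TransitionProbabilitySet", atol: float = 1e-9) -> bool:
        if not np.array_equal(self.years, other.years):
            return False
        return all(
            np.allclose(getattr(self, n), getattr(other, n), atol=atol, equal_nan=True)
            for n in _PROB_COLUMNS
        )
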