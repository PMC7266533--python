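"""Population life tables: expected mortality rates and expected survival.

A life table is a complete grid of mortality rates (per person-year) over
single-year age bands, single calendar years, sex and any number of extra
strata (e.g. deprivation group).  For a patient diagnosed at (possibly
fractional) age ``a`` in calendar year ``y``, the expected hazard at
follow-up time ``t`` is the rate of the band containing attained age
``floor(a + t)`` and attained year ``floor(y + t)``, both capped at the
table's last band (tables end in an open age band).  The expected hazard
is therefore piecewise constant along follow-up, with jumps where the
attained age or year crosses an integer, and the expected cumulative
hazard integrates it exactly segment by segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LifeTable",
    "ExpectedTrajectory",
    "read_life_table",
    "IncompleteLifeTableError",
]


class IncompleteLifeTableError(ValueError):
    """Raised when the declared age x year x sex x stratum grid has holes."""


@dataclass
class ExpectedTrajectory:
    """Expected mortality of one patient along follow-up time.

    ``survival = exp(-cum_hazard)`` with ``survival[times == 0] == 1``;
    ``hazard`` is the piecewise-constant band rate at each time.
    """

    times: np.ndarray
    hazard: np.ndarray
    cum_hazard: np.ndarray
    survival: np.ndarray
    patient_id: object = None


@dataclass
class _Path:
    """Breakpoints and per-segment rates of one patient's expected hazard."""

    breaks: np.ndarray      # 0 = b_0 < b_1 < ... < b_m = t_max
    rates: np.ndarray       # length m, rate on (b_{k-1}, b_k)
    cum: np.ndarray         # cumulative hazard at each break, cum[0] = 0

    def cum_hazard_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.breaks, self.cum)

    def survival_at(self, t: np.ndarray) -> np.ndarray:
        return np.exp(-self.cum_hazard_at(t))

    def hazard_at(self, t: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(self.breaks, t, side="right") - 1, 0,
                      len(self.rates) - 1)
        return self.rates[idx]


class LifeTable:
    """Complete grid of expected mortality rates.

    Parameters
    ----------
    frame : pandas.DataFrame
        Long format, one row per cell, with integer age and year columns,
        a sex column, zero or more stratum columns and a rate column.
    strata : sequence of str
        Names of the extra stratum columns (may be empty).
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        *,
        age: str = "age",
        year: str = "year",
        sex: str = "sex",
        strata=(),
        rate: str = "rate",
        rate_type: str = "hazard",
    ):
        strata = tuple(strata)
        needed = [age, year, sex, *strata, rate]
        missing = [c for c in needed if c not in frame.columns]
        if missing:
            raise ValueError(f"life table is missing column(s): {missing}")
        df = frame[needed].copy()
        df.columns = ["age", "year", "sex", *strata, "rate"]
        rates = pd.to_numeric(df["rate"], errors="coerce")
        if rates.isna().any():
            bad = df.loc[rates.isna()].iloc[0]
            raise ValueError(f"non-numeric rate in life table row {dict(bad)}")
        if rate_type == "probability":
            if (rates >= 1).any():
                raise ValueError("annual death probabilities must be < 1")
            rates = -np.log1p(-rates)
        elif rate_type != "hazard":
            raise ValueError("rate_type must be 'hazard' or 'probability'")
        if (rates < 0).any() or not np.isfinite(rates).all():
            bad = df.loc[(rates < 0) | ~np.isfinite(rates)].iloc[0]
            raise ValueError(f"negative or non-finite rate in life table: {dict(bad)}")
        df["rate"] = rates.astype(float)

        self.strata = strata
        self.ages = np.sort(df["age"].unique().astype(int))
        self.years = np.sort(df["year"].unique().astype(int))
        self.sexes = tuple(sorted(df["sex"].unique(), key=str))
        self.stratum_levels = {
            s: tuple(sorted(df[s].unique(), key=str)) for s in strata
        }
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("life-table ages must form a contiguous range")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("life-table years must form a contiguous range")

        # pivot each (sex, strata...) group into an age x year rate matrix
        self._grids: dict[tuple, np.ndarray] = {}
        n_age, n_year = len(self.ages), len(self.years)
        key_cols = ["sex", *strata]
        for key, g in df.groupby(key_cols, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            if g.duplicated(["age", "year"]).any():
                dup = g[g.duplicated(["age", "year"])].iloc[0]
                raise ValueError(f"duplicate life-table cell: {dict(dup)}")
            mat = np.full((n_age, n_year), np.nan)
            ai = g["age"].to_numpy(int) - self.ages[0]
            yi = g["year"].to_numpy(int) - self.years[0]
            mat[ai, yi] = g["rate"].to_numpy()
            if np.isnan(mat).any():
                a, y = np.argwhere(np.isnan(mat))[0]
                raise IncompleteLifeTableError(
                    "incomplete life table: no rate for "
                    f"(age={self.ages[0] + a}, year={self.years[0] + y}, "
                    f"sex={key[0]!r}"
                    + "".join(f", {s}={v!r}" for s, v in zip(strata, key[1:]))
                    + ")"
                )
            self._grids[key] = mat
        # grids cover the declared cross of sex x strata levels
        expected_keys = {
            (sx, *vals)
            for sx in self.sexes
            for vals in _product([self.stratum_levels[s] for s in strata])
        }
        missing_keys = expected_keys - set(self._grids)
        if missing_keys:
            k = sorted(missing_keys, key=str)[0]
            raise IncompleteLifeTableError(
                f"incomplete life table: no rows for sex/stratum combination {k!r}"
            )

    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self._grids) * len(self.ages) * len(self.years)

    def group_key(self, sex, stratum_values=()) -> tuple:
        key = (sex, *tuple(stratum_values))
        if key not in self._grids:
            raise KeyError(
                f"sex/stratum combination {key!r} not present in life table "
                f"(sexes={self.sexes}, strata={self.stratum_levels})"
            )
        return key

    def _grid(self, sex, stratum_values=()) -> np.ndarray:
        return self._grids[self.group_key(sex, stratum_values)]

    def expected_hazard_at(
        self, age_at_dx: float, year_at_dx: float, sex, stratum_values=(), t=0.0
    ) -> np.ndarray | float:
        """Band rate at follow-up time(s) ``t`` (capped at the edge bands)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be >= 0")
        grid = self._grid(sex, stratum_values)
        ai = np.clip(np.floor(age_at_dx + t).astype(int) - self.ages[0],
                     0, len(self.ages) - 1)
        yi = np.clip(np.floor(year_at_dx + t).astype(int) - self.years[0],
                     0, len(self.years) - 1)
        out = grid[ai, yi]
        return float(out) if out.ndim == 0 else out

    def _check_range(self, age_at_dx: float, year_at_dx: float) -> None:
        if age_at_dx < self.ages[0] or age_at_dx > self.ages[-1] + 1:
            logger.warning(
                "age at diagnosis %.1f outside life-table range [%d, %d]; "
                "capped at the edge band", age_at_dx, self.ages[0], self.ages[-1]
            )
        if year_at_dx < self.years[0] or year_at_dx > self.years[-1] + 1:
            logger.warning(
                "diagnosis year %.1f outside life-table range [%d, %d]; "
                "capped at the edge band", year_at_dx, self.years[0], self.years[-1]
            )

    def hazard_path(
        self, age_at_dx: float, year_at_dx: float, sex, stratum_values=(),
        t_max: float = 1.0
    ) -> _Path:
        """Piecewise-constant expected hazard on [0, t_max] for one patient."""
        self._check_range(age_at_dx, year_at_dx)
        grid = self._grid(sex, stratum_values)
        cross = []
        for start in (age_at_dx, year_at_dx):
            first = np.floor(start) + 1.0
            cross.append(np.arange(first, start + t_max) - start)
        breaks = np.unique(np.concatenate([[0.0], *cross, [t_max]]))
        breaks = breaks[(breaks >= 0.0) & (breaks <= t_max)]
        mids = 0.5 * (breaks[:-1] + breaks[1:])
        ai = np.clip(np.floor(age_at_dx + mids).astype(int) - self.ages[0],
                     0, len(self.ages) - 1)
        yi = np.clip(np.floor(year_at_dx + mids).astype(int) - self.years[0],
                     0, len(self.years) - 1)
        rates = grid[ai, yi]
        cum = np.concatenate([[0.0], np.cumsum(rates * np.diff(breaks))])
        return _Path(breaks=breaks, rates=rates, cum=cum)

    def expected_survival(
        self, age_at_dx: float, year_at_dx: float, sex, stratum_values=(),
        eval_times=(0.0,), patient_id=None,
    ) -> ExpectedTrajectory:
        """Expected hazard, cumulative hazard and survival S*(t) on a grid."""
        eval_times = np.asarray(eval_times, dtype=float)
        if np.any(eval_times < 0):
            raise ValueError("eval_times must be >= 0")
        if np.any(np.diff(eval_times) < 0):
            raise ValueError("eval_times must be non-decreasing")
        t_max = float(eval_times[-1]) if eval_times.size else 0.0
        path = self.hazard_path(age_at_dx, year_at_dx, sex, stratum_values,
                                t_max=max(t_max, 1e-12))
        cum = path.cum_hazard_at(eval_times)
        return ExpectedTrajectory(
            times=eval_times,
            hazard=path.hazard_at(eval_times),
            cum_hazard=cum,
            survival=np.exp(-cum),
            patient_id=patient_id,
        )

    # -- I/O -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, mat in sorted(self._grids.items(), key=lambda kv: tuple(map(str, kv[0]))):
            sex, *stratum = key
            for i, a in enumerate(self.ages):
                for j, y in enumerate(self.years):
                    rows.append((a, y, sex, *stratum, mat[i, j]))
        return pd.DataFrame(
            rows, columns=["age", "year", "sex", *self.strata, "rate"]
        )

    def write(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"LifeTable(ages {self.ages[0]}-{self.ages[-1]}, "
            f"years {self.years[0]}-{self.years[-1]}, sexes={self.sexes}, "
            f"strata={self.stratum_levels})"
        )


def _product(level_lists):
    if not level_lists:
        return [()]
    out = [()]
    for levels in level_lists:
        out = [t + (v,) for t in out for v in levels]
    return out


def read_life_table(
    path,
    schema: dict | None = None,
    sep: str = ",",
    rate_type: str = "hazard",
) -> LifeTable:
    """Read a delimited-text life table.

    ``schema`` maps the canonical names to the file's column names, e.g.
    ``{"age": "age", "year": "year", "sex": "sex", "strata": ["dep"],
    "rate": "rate"}``.  Default columns are ``age, year, sex, dep, rate``
    if a ``dep`` column exists, else no strata.  ``rate_type="probability"``
    converts annual death probabilities q to rates via -ln(1 - q).
    """
    df = pd.read_csv(path, sep=sep)
    schema = dict(schema or {})
    strata = schema.pop("strata", None)
    if strata is None:
        strata = ["dep"] if "dep" in df.columns else []
    names = {k: schema.get(k, k) for k in ("age", "year", "sex", "rate")}
    missing = [c for c in [*names.values(), *strata] if c not in df.columns]
    if missing:
        raise ValueError(
            f"life table file {path} is missing column(s): {missing}; "
            f"available: {list(df.columns)}"
        )
    return LifeTable(
        df,
        age=names["age"],
        year=names["year"],
        sex=names["sex"],
        strata=strata,
        rate=names["rate"],
        rate_type=rate_type,
    )
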