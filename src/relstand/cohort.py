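"""Patient-level cohort container for relative-survival analyses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lifetable import LifeTable

__all__ = ["Cohort"]


@dataclass
class Cohort:
    """A cohort of incident cases with life-table linkage information.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per patient.
    time, event, age, sex, year : str
        Column names for follow-up time (years, > 0), all-cause event
        indicator (0/1), age at diagnosis (years, may be fractional),
        sex (must use the life table's sex labels) and calendar year at
        diagnosis.
    exposure : str, optional
        Binary (0/1 or two-level) exposure column used for contrasts.
    lifetable_strata : tuple of str
        Cohort columns matching the life table's stratum dimensions, in
        the life table's stratum order.
    """

    data: pd.DataFrame
    time: str = "time"
    event: str = "event"
    age: str = "age"
    sex: str = "sex"
    year: str = "year"
    exposure: str | None = None
    lifetable_strata: tuple = ()

    def __post_init__(self):
        self.lifetable_strata = tuple(self.lifetable_strata)
        cols = [self.time, self.event, self.age, self.sex, self.year,
                *self.lifetable_strata]
        if self.exposure is not None:
            cols.append(self.exposure)
        missing = [c for c in dict.fromkeys(cols) if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort is missing column(s): {missing}")
        t = self.data[self.time].to_numpy(float)
        if not np.isfinite(t).all() or (t <= 0).any():
            raise ValueError("follow-up times must be positive and finite")
        d = self.data[self.event].to_numpy()
        if not np.isin(d, [0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        if self.exposure is not None:
            levels = np.unique(self.data[self.exposure])
            if len(levels) > 2:
                raise ValueError(
                    f"exposure {self.exposure!r} must be binary, got {levels!r}"
                )

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    def times(self) -> np.ndarray:
        return self.data[self.time].to_numpy(float)

    def events(self) -> np.ndarray:
        return self.data[self.event].to_numpy(float)

    def validate_against(self, table: LifeTable) -> None:
        """Every patient must resolve to a life-table sex/stratum group."""
        if len(self.lifetable_strata) != len(table.strata):
            raise ValueError(
                f"cohort declares life-table strata {self.lifetable_strata} "
                f"but the table has strata {table.strata}"
            )
        groups = self.data.groupby(
            [self.sex, *self.lifetable_strata], sort=False
        ).size()
        for key in groups.index:
            key = key if isinstance(key, tuple) else (key,)
            table.group_key(key[0], key[1:])

    def z1_records(self, records: pd.DataFrame | None = None):
        """(age, year, sex, stratum values) arrays for life-table lookups."""
        df = self.data if records is None else records
        stratum_vals = list(zip(*[df[c] for c in self.lifetable_strata])) \
            if self.lifetable_strata else [()] * len(df)
        return (
            df[self.age].to_numpy(float),
            df[self.year].to_numpy(float),
            df[self.sex].to_numpy(object),
            stratum_vals,
        )

    def subset(self, mask) -> "Cohort":
        return Cohort(
            self.data.loc[mask].reset_index(drop=True),
            time=self.time, event=self.event, age=self.age, sex=self.sex,
            year=self.year, exposure=self.exposure,
            lifetable_strata=self.lifetable_strata,
        )

    @classmethod
    def read(cls, path, sep: str = ",", **columns) -> "Cohort":
        return cls(pd.read_csv(path, sep=sep), **columns)

    def write(self, path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, index=False)
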