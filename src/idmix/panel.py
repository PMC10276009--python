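"""Containers for country × day multivariate panels.

A :class:`CountryPanel` holds, for each named variable, a units × dates table
of daily values (missing entries are NaN), plus optional per-unit population
metadata. The three variables in the motivating application are standardised
new cases per million population, new deaths per million population, and a
0–100 government-stringency index, but the containers are agnostic to what
the variables mean.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountryPanel",
    "StandardizedPanel",
    "StageWindow",
    "covid_stage_windows",
    "date_span_days",
]


def _as_date(d) -> _dt.date:
    if isinstance(d, _dt.datetime):
        return d.date()
    if isinstance(d, _dt.date):
        return d
    return pd.Timestamp(d).date()


@dataclass
class CountryPanel:
    """Aligned per-variable value tables over common unit and date axes.

    Parameters
    ----------
    variables
        Mapping from variable name to a DataFrame indexed by unit ID with a
        daily, contiguous ``DatetimeIndex`` as columns. All tables must share
        identical axes.
    population
        Optional per-unit population counts (positive), indexed like the
        variable tables.
    """

    variables: dict[str, pd.DataFrame]
    population: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("panel needs at least one variable")
        names = list(self.variables)
        ref = self.variables[names[0]]
        dates = pd.DatetimeIndex(ref.columns)
        if len(dates) > 1:
            deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
            if not np.all(deltas == 1):
                raise ValueError("dates must be strictly increasing and daily-contiguous")
        for name in names:
            tab = self.variables[name]
            if not tab.index.equals(ref.index) or not tab.columns.equals(ref.columns):
                raise ValueError(f"variable {name!r} axes differ from {names[0]!r}")
        if self.population is not None:
            missing = ref.index.difference(self.population.index)
            if len(missing):
                raise ValueError(f"population missing for units: {list(missing)}")
            self.population = self.population.loc[ref.index].astype(float)

    # -- axes ------------------------------------------------------------
    @property
    def units(self) -> list:
        return list(next(iter(self.variables.values())).index)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(next(iter(self.variables.values())).columns)

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_days(self) -> int:
        return len(self.dates)

    @property
    def variable_names(self) -> list[str]:
        return list(self.variables)

    # -- manipulation ----------------------------------------------------
    def subset_units(self, units) -> "CountryPanel":
        units = list(units)
        pop = self.population.loc[units] if self.population is not None else None
        return CountryPanel(
            {k: v.loc[units] for k, v in self.variables.items()}, population=pop
        )

    def subset_dates(self, start, end) -> "CountryPanel":
        start, end = pd.Timestamp(_as_date(start)), pd.Timestamp(_as_date(end))
        mask = (self.dates >= start) & (self.dates <= end)
        return CountryPanel(
            {k: v.loc[:, mask] for k, v in self.variables.items()},
            population=self.population,
        )

    def copy(self) -> "CountryPanel":
        pop = self.population.copy() if self.population is not None else None
        return CountryPanel({k: v.copy() for k, v in self.variables.items()}, pop)

    # -- IO ---------------------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        """Long format with columns (unit, date, variable, value)."""
        frames = []
        for name, tab in self.variables.items():
            melted = tab.reset_index(names="unit").melt(
                id_vars="unit", var_name="date", value_name="value"
            )
            melted["variable"] = name
            frames.append(melted)
        out = pd.concat(frames, ignore_index=True)
        return out[["unit", "date", "variable", "value"]]

    @classmethod
    def from_long(cls, df: pd.DataFrame, population: pd.Series | None = None) -> "CountryPanel":
        df = df.copy()
        df["date"] = pd.to_datetime(df["date"])
        variables = {}
        for name, grp in df.groupby("variable", sort=False):
            tab = grp.pivot(index="unit", columns="date", values="value")
            variables[str(name)] = tab.sort_index(axis=1)
        # align all variable tables on the union of axes
        units = variables[next(iter(variables))].index
        dates = variables[next(iter(variables))].columns
        variables = {k: v.reindex(index=units, columns=dates) for k, v in variables.items()}
        return cls(variables, population=population)

    def write_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, population_path=None) -> "CountryPanel":
        df = pd.read_csv(path)
        pop = None
        if population_path is not None:
            pop_df = pd.read_csv(population_path)
            pop = pop_df.set_index("unit")["population"]
        return cls.from_long(df, population=pop)


@dataclass
class StandardizedPanel(CountryPanel):
    """A :class:`CountryPanel` of z-scores plus the pooled moments used.

    ``means[k]`` and ``sds[k]`` are the pooled (all units × all days) mean and
    sample standard deviation of variable ``k`` before standardisation.
    """

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class StageWindow:
    """An inclusive calendar window used for temporal stratification."""

    label: int
    start: _dt.date
    end: _dt.date

    def __post_init__(self):
        object.__setattr__(self, "start", _as_date(self.start))
        object.__setattr__(self, "end", _as_date(self.end))
        if self.end < self.start:
            raise ValueError(f"window {self.label}: end precedes start")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


def covid_stage_windows() -> list[StageWindow]:
    """The four pandemic stages used to stratify the 2020–2021 panel."""
    return [
        StageWindow(1, _dt.date(2020, 3, 1), _dt.date(2020, 6, 23)),
        StageWindow(2, _dt.date(2020, 6, 24), _dt.date(2020, 10, 15)),
        StageWindow(3, _dt.date(2020, 10, 16), _dt.date(2021, 2, 6)),
        StageWindow(4, _dt.date(2021, 2, 7), _dt.date(2021, 5, 29)),
    ]


def date_span_days(start, end) -> int:
    """Span between two calendar dates as a plain difference in days.

    This is the "period of N days" convention used when quoting the length of
    the study window (the number of daily steps from start to end, i.e. one
    less than the inclusive day count).
    """
    return (_as_date(end) - _as_date(start)).days
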