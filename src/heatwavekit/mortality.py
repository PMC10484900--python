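"""State-level heat-wave mortality rates and their decadal change.

Heat-wave death counts are reported per state and year (1981–2019
style accidental-deaths tabulations); populations come from census
snapshots. The national rate for a year is Σ deaths / Σ population
(not a mean of state rates), expressed per million. Populations are
interpolated linearly between census years and held constant outside
them; a single census implies a constant denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

WINDOW_1 = (1981, 1999)
WINDOW_2 = (2000, 2019)


@dataclass(frozen=True)
class MortalityRecord:
    state: str
    year: int
    deaths: float  # count; synthetic tables may carry expected (fractional) counts
    population: float
    rate_pm: float  # deaths per million


def rate_per_million(deaths: float, population: float) -> float:
    """Deaths per million persons."""
    if population <= 0:
        raise ValidationError(f"population must be positive, got {population}")
    if deaths < 0:
        raise ValidationError(f"deaths must be non-negative, got {deaths}")
    return 1e6 * deaths / population


def read_mortality_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"state", "year", "deaths"}
    if not need.issubset(df.columns):
        raise FormatError(f"mortality table needs columns {sorted(need)}")
    return df


def read_population_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"state", "census_year", "population"}
    if not need.issubset(df.columns):
        raise FormatError(f"population table needs columns {sorted(need)}")
    return df


def interpolate_population(
    population: pd.DataFrame, states: Sequence[str], years: Sequence[int]
) -> pd.DataFrame:
    """Per-state annual population: linear between censuses, flat outside."""
    rows = []
    for state in states:
        sub = population[population["state"] == state].sort_values("census_year")
        if sub.empty:
            raise ValidationError(f"no census rows for state {state!r}")
        interp = np.interp(
            np.asarray(years, dtype=float),
            sub["census_year"].to_numpy(dtype=float),
            sub["population"].to_numpy(dtype=float),
        )
        rows.extend(
            {"state": state, "year": int(y), "population": float(p)}
            for y, p in zip(years, interp)
        )
    return pd.DataFrame(rows)


def build_records(
    mortality: pd.DataFrame, population: pd.DataFrame
) -> list[MortalityRecord]:
    """Join deaths with interpolated populations into rate records."""
    states = sorted(mortality["state"].unique())
    years = sorted(mortality["year"].unique())
    pop = interpolate_population(population, states, years)
    merged = mortality.merge(pop, on=["state", "year"], how="left")
    if merged["population"].isna().any():
        raise ValidationError("population missing for some state-years")
    return [
        MortalityRecord(
            state=r.state,
            year=int(r.year),
            deaths=float(r.deaths),
            population=float(r.population),
            rate_pm=rate_per_million(r.deaths, r.population),
        )
        for r in merged.itertuples(index=False)
    ]


def national_annual_rates(records: Sequence[MortalityRecord]) -> pd.Series:
    """National rate per million per year: Σ deaths / Σ population."""
    df = pd.DataFrame(
        {"year": [r.year for r in records], "deaths": [r.deaths for r in records],
         "population": [r.population for r in records]}
    )
    g = df.groupby("year").sum()
    return 1e6 * g["deaths"] / g["population"]


def decadal_change(
    records: Sequence[MortalityRecord],
    window1: tuple[int, int] = WINDOW_1,
    window2: tuple[int, int] = WINDOW_2,
) -> float:
    """Percent change of the mean national annual rate between two windows."""
    rates = national_annual_rates(records)
    r1 = rates[(rates.index >= window1[0]) & (rates.index <= window1[1])]
    r2 = rates[(rates.index >= window2[0]) & (rates.index <= window2[1])]
    if r1.empty or r2.empty:
        raise ValidationError("both comparison windows must contain data")
    m1, m2 = float(r1.mean()), float(r2.mean())
    if m1 == 0:
        raise ValidationError("first-window mean rate is zero; change undefined")
    return 100.0 * (m2 - m1) / m1
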