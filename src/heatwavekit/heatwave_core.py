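"""Effective thresholds, heat-wave spell detection, and season statistics.

A heat wave is operationally a run of at least three consecutive days
whose daily maximum temperature meets or exceeds the *effective
threshold* — the larger of (a) the 90th percentile of baseline
April–June daily Tmax and (b) the fixed zone cutoff (40 °C plains,
37 °C coast, 30 °C hilly). All statistics are confined to the 91-day
April–June (AMJ) pre-monsoon window.

Exceedance is inclusive (``tmax >= effective``), matching operational
"equal or exceed" definitions. A missing day (NaN) terminates a run.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .data_io import CitySeries
from .errors import InsufficientBaselineError, ValidationError
from .zones import Zone

MIN_SPELL_DAYS = 3
SEASON_DAYS = 91  # Apr 1 – Jun 30
#: seasons with more missing days than this are excluded from period means
MAX_MISSING_DAYS = 9

DEFAULT_BASELINE = (1950, 2010)


@dataclass(frozen=True)
class ThresholdSpec:
    """Effective heat-wave threshold for one city."""

    q90: float  # 90th percentile of baseline AMJ daily Tmax, °C
    zone_fixed: float  # fixed zone cutoff, °C
    baseline_window: tuple[int, int]  # inclusive year range

    @property
    def effective(self) -> float:
        return max(self.q90, self.zone_fixed)


@dataclass(frozen=True)
class Spell:
    """A detected heat-wave run within one AMJ season."""

    start_date: pd.Timestamp
    end_date: pd.Timestamp
    length: int  # days, ≥ 3
    peak_tmax: float  # max daily Tmax in the spell, °C
    mean_tmax: float  # mean daily Tmax in the spell, °C

    def __post_init__(self) -> None:
        expected = (self.end_date - self.start_date).days + 1
        if self.length != expected or self.length < MIN_SPELL_DAYS:
            raise ValidationError(
                f"inconsistent spell: length {self.length}, span {expected}"
            )


@dataclass(frozen=True)
class SeasonStats:
    """Per-season (one AMJ window) heat-wave characteristics."""

    year: int
    n_spells: int
    mean_duration: float  # mean spell length in days; 0.0 if no spells
    total_hw_days: int  # Σ spell lengths, ≤ 91
    intensity: float | None  # mean of per-spell peak Tmax, °C; None if no spells
    n_missing: int = 0  # missing days in the AMJ window


def amj_mask(dates: pd.DatetimeIndex, year: int | None = None) -> np.ndarray:
    """Boolean mask for April–June days (optionally of one year)."""
    m = dates.month.isin((4, 5, 6))
    if year is not None:
        m &= dates.year == year
    return np.asarray(m)


def compute_threshold(
    series: CitySeries,
    baseline: tuple[int, int] | None = None,
    zone: Zone | None = None,
) -> ThresholdSpec:
    """Build the effective threshold from a baseline climatology.

    ``q90`` is the 90th percentile (linear interpolation) of all AMJ
    daily Tmax values pooled over the baseline years. The effective
    threshold is ``max(q90, zone cutoff)``.
    """
    if baseline is None:
        baseline = DEFAULT_BASELINE
    if zone is None:
        zone = series.city.zone
    y0, y1 = baseline
    if y0 >= y1:
        raise ValidationError(f"baseline window start {y0} must precede end {y1}")
    mask = amj_mask(series.dates) & np.asarray(
        (series.dates.year >= y0) & (series.dates.year <= y1)
    )
    values = series.tmax[mask]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise InsufficientBaselineError(
            f"series for {series.city.city_id} has no AMJ data in {y0}–{y1}"
        )
    q90 = float(np.percentile(values, 90))
    return ThresholdSpec(q90=q90, zone_fixed=zone.fixed_threshold, baseline_window=(y0, y1))


def find_spells(series: CitySeries, threshold: ThresholdSpec, year: int) -> list[Spell]:
    """Detect heat-wave spells in one AMJ season.

    Maximal runs of days with ``tmax >= threshold.effective`` are
    enumerated after clipping to Apr 1–Jun 30; only runs of at least
    three days are kept. Missing days break runs. Spells come back
    disjoint and in chronological order.
    """
    mask = amj_mask(series.dates, year)
    dates = series.dates[mask]
    tmax = series.tmax[mask]
    hot = np.isfinite(tmax) & (tmax >= threshold.effective)
    spells: list[Spell] = []
    i = 0
    n = len(hot)
    while i < n:
        if hot[i]:
            j = i
            while j + 1 < n and hot[j + 1] and (dates[j + 1] - dates[j]).days == 1:
                j += 1
            length = j - i + 1
            if length >= MIN_SPELL_DAYS:
                window = tmax[i : j + 1]
                spells.append(
                    Spell(
                        start_date=dates[i],
                        end_date=dates[j],
                        length=length,
                        peak_tmax=float(np.max(window)),
                        mean_tmax=float(np.mean(window)),
                    )
                )
            i = j + 1
        else:
            i += 1
    return spells


def season_stats(spells: list[Spell], year: int, n_missing: int = 0) -> SeasonStats:
    """Summarize one season's spells into duration/frequency/intensity.

    Duration is the mean spell length (0 if no spells), frequency the
    spell count, intensity the mean of per-spell peak Tmax (None if no
    spells — a spell-free season has no defined intensity).
    """
    for a, b in zip(spells, spells[1:]):
        if a.end_date >= b.start_date:
            raise ValidationError(
                f"overlapping or unordered spells at {a.end_date.date()}"
            )
    for s in spells:
        if s.start_date.year != year or not (4 <= s.start_date.month <= 6):
            raise ValidationError(f"spell {s.start_date.date()} outside AMJ {year}")
    n = len(spells)
    total = sum(s.length for s in spells)
    if total > SEASON_DAYS:
        raise ValidationError(f"total heat-wave days {total} exceed season length")
    return SeasonStats(
        year=year,
        n_spells=n,
        mean_duration=float(np.mean([s.length for s in spells])) if n else 0.0,
        total_hw_days=total,
        intensity=float(np.mean([s.peak_tmax for s in spells])) if n else None,
        n_missing=n_missing,
    )


def analyze_series(
    series: CitySeries,
    threshold: ThresholdSpec,
    years: range | list[int],
) -> list[SeasonStats]:
    """Run spell detection and season summaries over a span of years."""
    out = []
    for year in years:
        mask = amj_mask(series.dates, year)
        if not mask.any():
            continue
        n_missing = int(np.sum(~np.isfinite(series.tmax[mask]))) + int(
            SEASON_DAYS - mask.sum()
        )
        spells = find_spells(series, threshold, year)
        out.append(season_stats(spells, year, n_missing=n_missing))
    return out
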