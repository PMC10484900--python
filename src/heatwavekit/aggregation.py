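"""Decadal-period aggregation, ensemble combination, zone summaries, changes.

Season statistics are pooled into four analysis periods — the
historical window 1981–2020 and three future windows D1 (2021–2046),
D2 (2047–2072), D3 (2073–2098) under an SSP scenario. Duration and
intensity period means condition on seasons that actually had a spell
("mean consecutive days" is meaningless over spell-free seasons);
frequency averages over all seasons, zeros included, because it is a
count. Ensemble members are combined by computing characteristics per
member first and then averaging — detection on an ensemble-mean field
would smear the extremes the analysis is about.

Zone summaries use a Student-t 95% confidence interval across cities,
treating cities as independent units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError
from .heatwave_core import MAX_MISSING_DAYS, SeasonStats
from .zones import Zone

METRICS = ("duration", "frequency", "intensity")

ENSEMBLE_ID = "ensemble"


@dataclass(frozen=True)
class Period:
    """An analysis window: historical or one of the future tranches."""

    label: str  # HIST | D1 | D2 | D3
    years: tuple[int, int]  # inclusive
    scenario: str  # historical | SSP245 | SSP585

    def __post_init__(self) -> None:
        hist = self.label == "HIST"
        if hist != (self.scenario == "historical"):
            raise ValidationError(
                "HIST pairs with the historical scenario; D1–D3 with an SSP"
            )

    def year_range(self) -> range:
        return range(self.years[0], self.years[1] + 1)


def standard_periods(scenario: str) -> list[Period]:
    """HIST plus the three future periods for one SSP scenario."""
    return [
        Period("HIST", (1981, 2020), "historical"),
        Period("D1", (2021, 2046), scenario),
        Period("D2", (2047, 2072), scenario),
        Period("D3", (2073, 2098), scenario),
    ]


@dataclass(frozen=True)
class PeriodStats:
    """Per-city duration/frequency/intensity for one period × scenario."""

    city_id: str
    period: Period
    member_id: str
    duration: float | None  # days; None when no season had a spell
    frequency: float  # mean spells per season, zero seasons included
    intensity: float | None  # °C; None when no season had a spell
    n_years_with_spells: float

    def metric(self, name: str) -> float | None:
        if name not in METRICS:
            raise ValidationError(f"unknown metric {name!r}; expected one of {METRICS}")
        return getattr(self, name)


@dataclass(frozen=True)
class ZoneSummary:
    """Across-city mean of one metric with a 95% Student-t interval."""

    zone: Zone
    period: Period
    metric: str
    mean: float
    ci_low: float | None
    ci_high: float | None
    n_cities: int


@dataclass(frozen=True)
class ChangeRecord:
    """Percent change of one metric between a baseline and a future period."""

    scope: str  # city_id or zone label
    metric: str
    baseline_value: float | None
    future_value: float | None
    pct_change: float | None
    new_occurrence: bool


def period_stats(
    seasons: Sequence[SeasonStats],
    period: Period,
    *,
    city_id: str = "",
    member_id: str = "",
    max_missing_days: int = MAX_MISSING_DAYS,
) -> PeriodStats:
    """Aggregate per-season statistics over one period.

    Seasons with more than ``max_missing_days`` missing days are
    excluded from all means.
    """
    if not seasons:
        raise ValidationError(f"no seasons supplied for period {period.label}")
    yrs = set(period.year_range())
    outside = [s.year for s in seasons if s.year not in yrs]
    if outside:
        raise ValidationError(
            f"seasons {sorted(set(outside))} outside period {period.label} {period.years}"
        )
    kept = [s for s in seasons if s.n_missing <= max_missing_days]
    if not kept:
        raise ValidationError(
            f"all seasons in period {period.label} excluded for missing data"
        )
    with_spells = [s for s in kept if s.n_spells > 0]
    duration = (
        float(np.mean([s.mean_duration for s in with_spells])) if with_spells else None
    )
    intensity = (
        float(np.mean([s.intensity for s in with_spells])) if with_spells else None
    )
    frequency = float(np.mean([s.n_spells for s in kept]))
    return PeriodStats(
        city_id=city_id,
        period=period,
        member_id=member_id,
        duration=duration,
        frequency=frequency,
        intensity=intensity,
        n_years_with_spells=float(len(with_spells)),
    )


def ensemble_combine(stats: Sequence[PeriodStats]) -> PeriodStats:
    """Average one city/period across ensemble members.

    Each metric is the unweighted mean over the members for which it is
    defined; the result carries ``member_id="ensemble"``.
    """
    if not stats:
        raise ValidationError("cannot combine an empty member list")
    first = stats[0]
    for s in stats[1:]:
        if s.city_id != first.city_id or s.period != first.period:
            raise ValidationError("members must share city and period")

    def _mean_defined(values: Iterable[float | None]) -> float | None:
        vals = [v for v in values if v is not None]
        return float(np.mean(vals)) if vals else None

    return PeriodStats(
        city_id=first.city_id,
        period=first.period,
        member_id=ENSEMBLE_ID,
        duration=_mean_defined(s.duration for s in stats),
        frequency=float(np.mean([s.frequency for s in stats])),
        intensity=_mean_defined(s.intensity for s in stats),
        n_years_with_spells=float(np.mean([s.n_years_with_spells for s in stats])),
    )


def t_interval(values: np.ndarray, confidence: float = 0.95) -> tuple[float, float, float]:
    """Mean and Student-t confidence bounds of a sample (n ≥ 2)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    half = float(sps.t.ppf(0.5 + confidence / 2.0, n - 1) * sd / np.sqrt(n))
    return mean, mean - half, mean + half


def zone_summary(
    stats: Sequence[PeriodStats],
    zone: Zone,
    metric: str,
    period: Period | None = None,
) -> ZoneSummary:
    """Across-city mean of one metric in a zone, with a 95% t-interval.

    With fewer than two cities the summary degenerates: the mean is the
    single value (or NaN) and the interval is undefined.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    if period is None:
        if not stats:
            raise ValidationError("empty stats list and no period given")
        period = stats[0].period
    values = np.array(
        [s.metric(metric) for s in stats if s.metric(metric) is not None], dtype=float
    )
    if values.size < 2:
        mean = float(values[0]) if values.size else float("nan")
        return ZoneSummary(zone, period, metric, mean, None, None, int(values.size))
    mean, lo, hi = t_interval(values)
    return ZoneSummary(zone, period, metric, mean, lo, hi, int(values.size))


def percent_change(
    baseline: PeriodStats, future: PeriodStats, metric: str
) -> ChangeRecord:
    """Relative change of one metric between two periods of one city.

    A baseline with zero heat-wave activity cannot anchor a percentage;
    such cities get ``new_occurrence=True`` and no ``pct_change`` —
    they are reported separately, never folded into zone means.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    if baseline.city_id != future.city_id:
        raise ValidationError("baseline and future must describe the same city")
    b = baseline.metric(metric)
    f = future.metric(metric)
    zero_activity = baseline.n_years_with_spells == 0 or (
        metric == "frequency" and (b is None or b == 0)
    )
    if zero_activity or b is None or b == 0:
        return ChangeRecord(
            scope=baseline.city_id,
            metric=metric,
            baseline_value=b,
            future_value=f,
            pct_change=None,
            new_occurrence=True,
        )
    pct = 100.0 * (f - b) / b if f is not None else None
    return ChangeRecord(
        scope=baseline.city_id,
        metric=metric,
        baseline_value=b,
        future_value=f,
        pct_change=pct,
        new_occurrence=False,
    )


def zone_percent_change(
    baseline: Sequence[PeriodStats],
    future: Sequence[PeriodStats],
    zone: Zone,
    metric: str,
) -> ChangeRecord:
    """Percent change of the zone's across-city mean.

    Cities with no baseline activity (new occurrences) are excluded
    from both the baseline and the future term, so the two means cover
    the same city set.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    fut_by_city = {s.city_id: s for s in future}
    b_vals, f_vals = [], []
    for b in baseline:
        f = fut_by_city.get(b.city_id)
        if f is None:
            continue
        rec = percent_change(b, f, metric)
        if rec.new_occurrence or rec.baseline_value is None:
            continue
        if rec.future_value is None:
            continue
        b_vals.append(rec.baseline_value)
        f_vals.append(rec.future_value)
    if not b_vals:
        return ChangeRecord(zone.value, metric, None, None, None, True)
    bm = float(np.mean(b_vals))
    fm = float(np.mean(f_vals))
    pct = 100.0 * (fm - bm) / bm if bm != 0 else None
    return ChangeRecord(zone.value, metric, bm, fm, pct, pct is None)
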