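"""Threshold construction, spell detection, and season statistics."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatwavekit.errors import InsufficientBaselineError, ValidationError
from heatwavekit.heatwave_core import (
    Spell,
    ThresholdSpec,
    compute_threshold,
    find_spells,
    season_stats,
)

from .conftest import constant_series, make_series


def sort_based_percentile(values, q: float) -> float:
    """Independent linear-interpolation percentile (sort and index)."""
    v = sorted(values)
    h = (len(v) - 1) * q
    f = math.floor(h)
    c = min(f + 1, len(v) - 1)
    return v[f] + (h - f) * (v[c] - v[f])


def brute_force_runs(hot: list[bool], min_len: int = 3) -> list[tuple[int, int]]:
    """All maximal runs of True of length ≥ min_len, as (start, end) indices."""
    runs = []
    for flag, group in itertools.groupby(enumerate(hot), key=lambda t: t[1]):
        idx = [i for i, _ in group]
        if flag and len(idx) >= min_len:
            runs.append((idx[0], idx[-1]))
    return runs


def pattern_series(city, year: int, hot: list[bool], thr: float = 40.0):
    tmax = np.where(hot, thr + 1.0, thr - 1.0)
    return make_series(city, year, tmax)


THRESHOLD = ThresholdSpec(q90=0.0, zone_fixed=40.0, baseline_window=(1950, 2010))


class TestThreshold:
    def test_fixed_cutoff_dominates_cool_series(self, coast_city):
        series = constant_series(coast_city, (1990, 1995), 35.0)
        thr = compute_threshold(series, (1990, 1995))
        assert thr.q90 == 35.0
        assert thr.effective == 37.0

    def test_percentile_dominates_hot_series(self, plains_city):
        series = constant_series(plains_city, (1990, 1995), 42.0)
        thr = compute_threshold(series, (1990, 1995))
        assert thr.effective == 42.0

    def test_q90_matches_sort_based_oracle(self, plains_city):
        rng = np.random.default_rng(123)
        dates = pd.date_range("1990-01-01", "2000-12-31", freq="D")
        tmax = rng.uniform(20.0, 45.0, len(dates))
        from heatwavekit.data_io import CitySeries

        series = CitySeries(plains_city, dates, tmax)
        thr = compute_threshold(series, (1990, 2000))
        amj = tmax[np.asarray(dates.month.isin((4, 5, 6)))]
        assert thr.q90 == pytest.approx(sort_based_percentile(amj, 0.9), rel=1e-12)

    def test_no_baseline_overlap_raises(self, plains_city):
        series = constant_series(plains_city, (2015, 2018), 41.0)
        with pytest.raises(InsufficientBaselineError):
            compute_threshold(series, (1950, 2010))

    def test_inverted_window_rejected(self, plains_city):
        series = constant_series(plains_city, (1990, 1995), 41.0)
        with pytest.raises(ValidationError):
            compute_threshold(series, (1995, 1990))


class TestFindSpells:
    def test_single_three_day_block(self, plains_city):
        tmax = np.full(91, 38.0)
        tmax[10:13] = 41.0
        series = make_series(plains_city, 2000, tmax)
        (spell,) = find_spells(series, THRESHOLD, 2000)
        assert spell.length == 3
        assert spell.peak_tmax == 41.0
        assert spell.start_date == pd.Timestamp("2000-04-11")

    def test_two_hot_days_are_no_spell(self, plains_city):
        tmax = np.full(91, 38.0)
        tmax[10:12] = 41.0
        series = make_series(plains_city, 2000, tmax)
        assert find_spells(series, THRESHOLD, 2000) == []

    def test_exceedance_is_inclusive(self, plains_city):
        series = make_series(plains_city, 2000, np.full(91, 40.0))
        (spell,) = find_spells(series, THRESHOLD, 2000)
        assert spell.length == 91

    def test_missing_day_breaks_run(self, plains_city):
        tmax = np.full(91, 38.0)
        tmax[10:17] = 41.0
        tmax[13] = np.nan
        series = make_series(plains_city, 2000, tmax)
        spells = find_spells(series, THRESHOLD, 2000)
        assert [s.length for s in spells] == [3, 3]

    def test_run_straddling_june_30_is_clipped(self, plains_city):
        dates = pd.date_range("2000-04-01", "2000-07-10", freq="D")
        tmax = np.full(len(dates), 38.0)
        tmax[-15:] = 41.0  # Jun 26 – Jul 10; only Jun 26–30 inside AMJ
        from heatwavekit.data_io import CitySeries

        series = CitySeries(plains_city, dates, tmax)
        (spell,) = find_spells(series, THRESHOLD, 2000)
        assert spell.length == 5
        assert spell.end_date == pd.Timestamp("2000-06-30")

    def test_random_patterns_match_brute_force(self, plains_city):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            hot = list(rng.random(91) < rng.uniform(0.1, 0.7))
            series = pattern_series(plains_city, 2000, hot)
            got = [
                (
                    (s.start_date - pd.Timestamp("2000-04-01")).days,
                    (s.end_date - pd.Timestamp("2000-04-01")).days,
                )
                for s in find_spells(series, THRESHOLD, 2000)
            ]
            assert got == brute_force_runs(hot)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_raising_threshold_never_adds_heat_wave_days(self, seed):
        rng = np.random.default_rng(seed)
        tmax = rng.uniform(36.0, 44.0, 91)
        from heatwavekit.data_io import CitySeries, City
        from heatwavekit.zones import Zone

        city = City("c", "C", 25.0, 80.0, Zone.NORTH_CENTRAL)
        dates = pd.date_range("2000-04-01", "2000-06-30", freq="D")
        series = CitySeries(city, dates, tmax)
        prev_days, prev_n = 92, 92
        for eff in (38.0, 40.0, 42.0):
            thr = ThresholdSpec(q90=eff, zone_fixed=40.0, baseline_window=(1950, 2010))
            spells = find_spells(series, thr, 2000)
            days = sum(s.length for s in spells)
            assert days <= prev_days
            prev_days = days
            assert all(np.all(s.peak_tmax >= thr.effective) for s in spells)


class TestSeasonStats:
    def _spell(self, year, start_day, length, peak):
        start = pd.Timestamp(f"{year}-04-01") + pd.Timedelta(days=start_day)
        return Spell(
            start_date=start,
            end_date=start + pd.Timedelta(days=length - 1),
            length=length,
            peak_tmax=peak,
            mean_tmax=peak,
        )

    def test_duration_frequency_intensity(self):
        spells = [self._spell(2000, 0, 3, 41.0), self._spell(2000, 10, 5, 43.0)]
        stats = season_stats(spells, 2000)
        assert stats.mean_duration == 4.0
        assert stats.n_spells == 2
        assert stats.intensity == 42.0
        assert stats.total_hw_days == 8

    def test_empty_season(self):
        stats = season_stats([], 2000)
        assert stats.n_spells == 0
        assert stats.mean_duration == 0.0
        assert stats.intensity is None

    def test_overlapping_spells_rejected(self):
        spells = [self._spell(2000, 0, 5, 41.0), self._spell(2000, 3, 3, 42.0)]
        with pytest.raises(ValidationError):
            season_stats(spells, 2000)
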