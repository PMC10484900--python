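"""Period aggregation, ensemble combination, zone CIs, percent changes."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from heatwavekit.aggregation import (
    Period,
    PeriodStats,
    ensemble_combine,
    percent_change,
    period_stats,
    standard_periods,
    t_interval,
    zone_percent_change,
    zone_summary,
)
from heatwavekit.errors import ValidationError
from heatwavekit.heatwave_core import SeasonStats
from heatwavekit.zones import Zone

HIST = Period("HIST", (1981, 2020), "historical")
D1 = Period("D1", (2021, 2046), "SSP245")


def season(year, n, dur, inten, missing=0):
    return SeasonStats(
        year=year,
        n_spells=n,
        mean_duration=dur,
        total_hw_days=int(n * dur),
        intensity=inten,
        n_missing=missing,
    )


def pstats(city_id="c1", period=HIST, member="", dur=4.0, freq=1.0, inten=42.0, nyrs=10.0):
    return PeriodStats(city_id, period, member, dur, freq, inten, nyrs)


class TestPeriodStats:
    def test_means_over_seasons(self):
        seasons = [season(1990, 1, 3.0, 41.0), season(1991, 1, 5.0, 43.0)]
        ps = period_stats(seasons, HIST, city_id="c1")
        assert ps.duration == 4.0
        assert ps.frequency == 1.0
        assert ps.intensity == 42.0
        assert ps.n_years_with_spells == 2.0

    def test_spell_free_period_is_undefined_not_zero(self):
        seasons = [season(y, 0, 0.0, None) for y in (1990, 1991, 1992)]
        ps = period_stats(seasons, HIST)
        assert ps.frequency == 0.0
        assert ps.duration is None
        assert ps.intensity is None
        assert ps.n_years_with_spells == 0.0

    def test_zero_spell_seasons_dilute_frequency_but_not_duration(self):
        seasons = [season(1990, 2, 4.0, 42.0), season(1991, 0, 0.0, None)]
        ps = period_stats(seasons, HIST)
        assert ps.frequency == 1.0  # zero season counts
        assert ps.duration == 4.0  # zero season does not

    def test_high_missing_season_excluded(self):
        seasons = [season(1990, 1, 3.0, 41.0), season(1991, 1, 9.0, 45.0, missing=30)]
        ps = period_stats(seasons, HIST)
        assert ps.duration == 3.0
        assert ps.n_years_with_spells == 1.0

    def test_season_outside_period_rejected(self):
        with pytest.raises(ValidationError):
            period_stats([season(2030, 1, 3.0, 41.0)], HIST)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            period_stats([], HIST)


class TestEnsembleCombine:
    def test_identical_members_unchanged(self):
        members = [pstats(member=f"m{i}") for i in range(3)]
        combined = ensemble_combine(members)
        assert combined.member_id == "ensemble"
        assert combined.duration == 4.0
        assert combined.frequency == 1.0

    def test_mean_of_two_members(self):
        combined = ensemble_combine(
            [pstats(member="a", dur=4.0), pstats(member="b", dur=6.0)]
        )
        assert combined.duration == 5.0

    def test_undefined_members_excluded_from_mean(self):
        combined = ensemble_combine(
            [
                pstats(member="a", dur=4.0, inten=42.0),
                pstats(member="b", dur=None, inten=None, nyrs=0.0, freq=0.0),
            ]
        )
        assert combined.duration == 4.0
        assert combined.frequency == 0.5

    def test_permutation_invariance(self):
        members = [pstats(member=f"m{i}", dur=float(i + 3)) for i in range(5)]
        a = ensemble_combine(members)
        b = ensemble_combine(members[::-1])
        assert a == b

    def test_mixed_cities_rejected(self):
        with pytest.raises(ValidationError):
            ensemble_combine([pstats(city_id="a"), pstats(city_id="b")])


class TestZoneSummary:
    def test_all_equal_gives_zero_width(self):
        stats = [pstats(city_id=f"c{i}", dur=4.0) for i in range(5)]
        zs = zone_summary(stats, Zone.NORTH_CENTRAL, "duration")
        assert zs.mean == zs.ci_low == zs.ci_high == 4.0

    def test_two_city_interval_matches_closed_form(self):
        stats = [pstats(city_id="a", dur=3.0), pstats(city_id="b", dur=5.0)]
        zs = zone_summary(stats, Zone.NORTH_CENTRAL, "duration")
        sd = np.std([3.0, 5.0], ddof=1)
        half = sps.t.ppf(0.975, 1) * sd / np.sqrt(2)
        assert zs.mean == 4.0
        assert zs.ci_low == pytest.approx(4.0 - half, rel=1e-12)
        assert zs.ci_high == pytest.approx(4.0 + half, rel=1e-12)

    def test_single_city_degenerates(self):
        zs = zone_summary([pstats(dur=4.0)], Zone.HILLY, "duration")
        assert zs.mean == 4.0
        assert zs.ci_low is None and zs.ci_high is None
        assert zs.n_cities == 1

    def test_t_interval_contains_mean(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(10.0, 2.0, 12)
        mean, lo, hi = t_interval(vals)
        assert lo <= mean <= hi


class TestPercentChange:
    def test_doubling_is_plus_100(self):
        rec = percent_change(pstats(dur=3.0), pstats(period=D1, dur=6.0), "duration")
        assert rec.pct_change == pytest.approx(100.0)
        assert not rec.new_occurrence

    def test_identity_is_zero(self):
        rec = percent_change(pstats(dur=4.0), pstats(period=D1, dur=4.0), "duration")
        assert rec.pct_change == 0.0

    def test_zero_baseline_flags_new_occurrence(self):
        base = pstats(dur=None, freq=0.0, inten=None, nyrs=0.0)
        rec = percent_change(base, pstats(period=D1, dur=5.0), "duration")
        assert rec.new_occurrence
        assert rec.pct_change is None

    @given(st.floats(-0.9, 5.0), st.floats(0.5, 50.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scaling_identity(self, x, b):
        rec = percent_change(
            pstats(dur=b), pstats(period=D1, dur=b * (1.0 + x)), "duration"
        )
        assert rec.pct_change == pytest.approx(100.0 * x, rel=1e-9, abs=1e-9)


class TestZonePercentChange:
    def test_new_occurrence_cities_excluded_from_both_terms(self):
        base = [
            pstats(city_id="a", dur=4.0),
            pstats(city_id="b", dur=None, freq=0.0, inten=None, nyrs=0.0),
        ]
        fut = [
            pstats(city_id="a", period=D1, dur=6.0),
            pstats(city_id="b", period=D1, dur=10.0),
        ]
        rec = zone_percent_change(base, fut, Zone.NORTH_CENTRAL, "duration")
        assert rec.baseline_value == 4.0
        assert rec.future_value == 6.0
        assert rec.pct_change == pytest.approx(50.0)


def test_standard_periods_cover_study_windows():
    periods = standard_periods("SSP585")
    assert [(p.label, p.years) for p in periods] == [
        ("HIST", (1981, 2020)),
        ("D1", (2021, 2046)),
        ("D2", (2047, 2072)),
        ("D3", (2073, 2098)),
    ]
    assert periods[0].scenario == "historical"
    assert all(p.scenario == "SSP585" for p in periods[1:])


def test_hist_label_requires_historical_scenario():
    with pytest.raises(ValidationError):
        Period("HIST", (1981, 2020), "SSP245")
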