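"""Synthetic gridded Tmax, city, and mortality fixtures with known truth.

The generator emulates the two temperature products the pipeline
consumes — a coarse (1°) observed-style historical grid and a finer
(0.25°) model-style scenario ensemble — without any download. Daily
Tmax in each cell is

    climatology(day of year) + warming trend · t + AR(1) anomaly,

where the climatology is a per-zone cosine annual cycle peaking in
mid-May (the Indian pre-monsoon maximum), the trend is a per-scenario
linear rate in °C/decade, and the anomaly is a stationary first-order
autoregressive process — the simplest noise with realistic day-to-day
persistence, which is what exercises run-length logic.

Heat-wave spells can be injected deterministically. An injected spell
holds a *uniform* temperature of (zone cutoff + exceedance) for its
whole length, and while injection is active the background is capped
0.5 °C below the zone cutoff everywhere. Because the effective
detection threshold is never below the zone cutoff and never below the
background, every injected spell is either recovered whole (its level
meets the threshold) or absent whole — never truncated — so duration,
frequency, and intensity have closed-form ground truth regardless of
where the baseline 90th percentile lands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .data_io import City, TemperatureGrid, write_city_table, write_tmax_grid
from .errors import ValidationError
from .heatwave_core import MIN_SPELL_DAYS, SEASON_DAYS
from .zones import Zone

#: (annual-mean Tmax °C, seasonal half-amplitude °C) per zone
DEFAULT_CLIMATOLOGY: dict[Zone, tuple[float, float]] = {
    Zone.HILLY: (21.0, 7.0),
    Zone.NORTHEAST: (27.0, 5.0),
    Zone.NORTHWEST: (33.0, 8.0),
    Zone.NORTH_CENTRAL: (32.0, 8.0),
    Zone.INTERIOR_PENINSULA: (33.0, 5.0),
    Zone.WEST_COAST: (31.5, 3.5),
    Zone.EAST_COAST: (32.5, 4.0),
}

#: linear warming trend in °C per decade, per scenario
DEFAULT_TRENDS: dict[str, float] = {
    "historical": 0.15,
    "SSP245": 0.35,
    "SSP585": 0.60,
}

PEAK_DOY = 135  # mid-May pre-monsoon maximum
CAP_MARGIN = 0.5  # °C the capped background stays below the zone cutoff
N_MEMBERS_DEFAULT = 13


@dataclass(frozen=True)
class SpellSpec:
    """One injected heat-wave spell with closed-form ground truth."""

    cell: tuple[int, int]  # (lat index, lon index)
    year: int
    start_day: int  # 0-based offset from Apr 1
    length: int  # days, ≥ 3
    exceedance: float  # °C above the zone cutoff; the spell's uniform level

    def level(self, zone: Zone) -> float:
        return zone.fixed_threshold + self.exceedance


@dataclass
class SyntheticConfig:
    """Full description of one synthetic temperature grid."""

    seed: int
    years: tuple[int, int] = (1981, 2020)
    grid_shape: tuple[int, int] = (2, 2)
    resolution_deg: float = 1.0
    lat0: float = 8.0
    lon0: float = 68.0
    zone_layout: list[list[Zone]] | None = None  # default: all NorthCentral
    climatology: dict[Zone, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLIMATOLOGY)
    )
    trend: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRENDS))
    ar1_phi: float = 0.7
    anomaly_sd: float = 1.5
    scenario: str = "historical"
    source_kind: str = "observed"
    member_id: str = ""
    reference_year: int = 1981  # trend is zero at Jan 1 of this year
    injected_spells: list[SpellSpec] = field(default_factory=list)
    n_members: int = N_MEMBERS_DEFAULT

    def layout(self) -> list[list[Zone]]:
        nlat, nlon = self.grid_shape
        if self.zone_layout is None:
            return [[Zone.NORTH_CENTRAL] * nlon for _ in range(nlat)]
        return self.zone_layout

    def cell_zone(self, cell: tuple[int, int]) -> Zone:
        return self.layout()[cell[0]][cell[1]]


def _validate_spells(config: SyntheticConfig) -> None:
    nlat, nlon = config.grid_shape
    y0, y1 = config.years
    by_cell_year: dict[tuple, list[SpellSpec]] = {}
    for s in config.injected_spells:
        iy, ix = s.cell
        if not (0 <= iy < nlat and 0 <= ix < nlon):
            raise ValidationError(f"spell cell {s.cell} outside grid {config.grid_shape}")
        if not (y0 <= s.year <= y1):
            raise ValidationError(f"spell year {s.year} outside {config.years}")
        if s.length < MIN_SPELL_DAYS:
            raise ValidationError(f"spell length {s.length} below minimum {MIN_SPELL_DAYS}")
        if s.start_day < 0 or s.start_day + s.length > SEASON_DAYS:
            raise ValidationError(
                f"spell days [{s.start_day}, {s.start_day + s.length}) leave "
                f"the {SEASON_DAYS}-day Apr–Jun window"
            )
        if s.exceedance <= 0:
            raise ValidationError("spell exceedance must be positive")
        by_cell_year.setdefault((s.cell, s.year), []).append(s)
    for key, group in by_cell_year.items():
        group.sort(key=lambda s: s.start_day)
        for a, b in zip(group, group[1:]):
            if b.start_day <= a.start_day + a.length:
                raise ValidationError(
                    f"spells in cell/year {key} overlap or touch; need a "
                    "sub-threshold gap day between spells"
                )


def generate_grid(config: SyntheticConfig) -> TemperatureGrid:
    """Generate one deterministic daily Tmax grid from a config."""
    _validate_spells(config)
    if not (0.0 <= config.ar1_phi < 1.0):
        raise ValidationError("ar1_phi must lie in [0, 1)")
    if config.scenario not in config.trend:
        raise ValidationError(f"no trend specified for scenario {config.scenario!r}")
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.years
    times = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    nt = len(times)
    nlat, nlon = config.grid_shape
    lats = config.lat0 + np.arange(nlat) * config.resolution_deg
    lons = config.lon0 + np.arange(nlon) * config.resolution_deg
    layout = config.layout()

    doy = times.dayofyear.to_numpy()
    annual = np.cos(2 * np.pi * (doy - PEAK_DOY) / 365.25)
    year_frac = (times.year.to_numpy() - config.reference_year) + (doy - 1) / 365.25
    trend_rate = config.trend[config.scenario] / 10.0  # °C per year
    warming = trend_rate * year_frac

    inject = bool(config.injected_spells)
    cube = np.empty((nt, nlat, nlon))
    for iy in range(nlat):
        for ix in range(nlon):
            zone = layout[iy][ix]
            mean, amp = config.climatology[zone]
            clim = mean + amp * annual
            eps = rng.standard_normal(nt)
            innov_sd = config.anomaly_sd * np.sqrt(1.0 - config.ar1_phi**2)
            anom = lfilter([1.0], [1.0, -config.ar1_phi], innov_sd * eps)
            series = clim + warming + anom
            if inject:
                series = np.minimum(series, zone.fixed_threshold - CAP_MARGIN)
            cube[:, iy, ix] = series

    if inject:
        for s in config.injected_spells:
            zone = config.cell_zone(s.cell)
            start = pd.Timestamp(year=s.year, month=4, day=1) + pd.Timedelta(
                days=s.start_day
            )
            i0 = times.get_loc(start)
            cube[i0 : i0 + s.length, s.cell[0], s.cell[1]] = s.level(zone)

    return TemperatureGrid(
        times=times,
        lats=lats,
        lons=lons,
        tmax=cube,
        source_kind=config.source_kind,
        scenario=config.scenario,
        member_id=config.member_id,
        resolution_deg=config.resolution_deg,
    )


def member_name(i: int) -> str:
    return f"synGCM{i + 1:02d}"


def generate_ensemble(config: SyntheticConfig) -> list[TemperatureGrid]:
    """Generate ``config.n_members`` grids with distinct member seeds."""
    if config.n_members < 1:
        raise ValidationError("ensemble needs at least one member")
    grids = []
    for i in range(config.n_members):
        member_seed = int((config.seed * 1_000_003 + 7_919 * (i + 1)) % 2**31)
        member_cfg = replace(
            config,
            seed=member_seed,
            member_id=member_name(i),
            source_kind="model",
        )
        grids.append(generate_grid(member_cfg))
    return grids


def random_spell_schedule(
    seed: int,
    cells: Sequence[tuple[int, int]],
    years: Sequence[int],
    max_per_season: int = 4,
    length_range: tuple[int, int] = (3, 10),
    exceedance_range: tuple[float, float] = (1.0, 5.0),
) -> list[SpellSpec]:
    """Draw a random but valid injection schedule (gaps ≥ 1 day)."""
    rng = np.random.default_rng(seed)
    spells: list[SpellSpec] = []
    for cell in cells:
        for year in years:
            n = int(rng.integers(0, max_per_season + 1))
            cursor = 0
            for _ in range(n):
                length = int(rng.integers(length_range[0], length_range[1] + 1))
                latest = SEASON_DAYS - length
                if cursor > latest:
                    break
                start = int(rng.integers(cursor, latest + 1))
                spells.append(
                    SpellSpec(
                        cell=cell,
                        year=year,
                        start_day=start,
                        length=length,
                        exceedance=float(
                            rng.uniform(exceedance_range[0], exceedance_range[1])
                        ),
                    )
                )
                cursor = start + length + 1
    return spells


def expected_season_truth(
    config: SyntheticConfig,
    cell: tuple[int, int],
    year: int,
    effective_threshold: float,
) -> tuple[int, float, float | None]:
    """Closed-form (n_spells, mean_duration, intensity) for one cell-season.

    Only spells whose uniform level meets the threshold are counted;
    the rest are invisible to detection by construction.
    """
    zone = config.cell_zone(cell)
    kept = [
        s
        for s in config.injected_spells
        if s.cell == cell and s.year == year and s.level(zone) >= effective_threshold
    ]
    if not kept:
        return 0, 0.0, None
    lengths = [s.length for s in kept]
    peaks = [s.level(zone) for s in kept]
    return len(kept), float(np.mean(lengths)), float(np.mean(peaks))


def generate_cities(
    seed: int,
    n: int,
    config: SyntheticConfig,
    states: Sequence[str] = ("StateA", "StateB", "StateC"),
) -> list[City]:
    """Place ``n`` cities on random grid cells, zones taken from the layout.

    Cities are jittered within a quarter cell of the cell center, so the
    nearest-cell rule maps each city back to the cell that named its zone.
    """
    rng = np.random.default_rng(seed)
    nlat, nlon = config.grid_shape
    layout = config.layout()
    cities = []
    for i in range(n):
        iy = int(rng.integers(0, nlat))
        ix = int(rng.integers(0, nlon))
        jit = config.resolution_deg / 4.0
        cities.append(
            City(
                city_id=f"city{i + 1:03d}",
                name=f"Synthetic City {i + 1}",
                lat=float(config.lat0 + iy * config.resolution_deg + rng.uniform(-jit, jit)),
                lon=float(config.lon0 + ix * config.resolution_deg + rng.uniform(-jit, jit)),
                zone=layout[iy][ix],
                state=str(states[i % len(states)]),
            )
        )
    return cities


def generate_mortality(
    seed: int,
    target_ratio: float = 1.5386,
    n_states: int = 10,
    years: tuple[int, int] = (1981, 2019),
    split_year: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic mortality + population tables with a fixed decadal ratio.

    The national mean annual rate over [split_year, end] is
    ``target_ratio`` times the mean over [start, split_year-1], exactly
    by construction (populations constant, second-window deaths scaled
    around the target mean with a zero-mean perturbation).
    """
    if target_ratio < 0:
        raise ValidationError("target_ratio must be non-negative")
    rng = np.random.default_rng(seed)
    states = [f"State{chr(ord('A') + i)}" for i in range(n_states)]
    pops = rng.uniform(5e6, 9e7, size=n_states)
    population = pd.DataFrame(
        {"state": states, "census_year": 2011, "population": pops}
    )
    y0, y1 = years
    w1 = np.arange(y0, split_year)
    w2 = np.arange(split_year, y1 + 1)
    d1 = rng.uniform(500.0, 3000.0, size=len(w1))
    mean2 = target_ratio * d1.mean()
    pert = rng.uniform(-0.3, 0.3, size=len(w2))
    pert -= pert.mean()
    d2 = mean2 * (1.0 + pert)
    rows = []
    for year, total in zip(np.concatenate([w1, w2]), np.concatenate([d1, d2])):
        w = rng.dirichlet(np.ones(n_states))
        for state, share in zip(states, w):
            rows.append({"state": state, "year": int(year), "deaths": total * share})
    return pd.DataFrame(rows), population


#: a compact layout exercising all seven zones on a 3×3 grid
STUDY_LAYOUT: list[list[Zone]] = [
    [Zone.HILLY, Zone.NORTHEAST, Zone.NORTHWEST],
    [Zone.NORTH_CENTRAL, Zone.INTERIOR_PENINSULA, Zone.WEST_COAST],
    [Zone.EAST_COAST, Zone.NORTH_CENTRAL, Zone.INTERIOR_PENINSULA],
]


def write_study(
    seed: int,
    out_dir,
    *,
    years_hist: tuple[int, int] = (1981, 2020),
    years_future: tuple[int, int] = (2021, 2098),
    n_members: int = 3,
    scenarios: Sequence[str] = ("SSP245", "SSP585"),
    n_cities: int = 14,
    grid_format: str = "netcdf",
    target_ratio: float = 1.5386,
) -> "Path":
    """Write a complete self-contained study fixture to ``out_dir``.

    Emits a historical grid, per-scenario ensemble member grids, a city
    table, mortality and population tables, and a ``config.yaml`` that
    :func:`heatwavekit.pipeline.run_pipeline` can consume directly.
    Returns the config path. Everything is deterministic in ``seed``.
    """
    from pathlib import Path

    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "csv" if grid_format == "csv" else "nc"

    base_cfg = SyntheticConfig(
        seed=seed,
        years=years_hist,
        grid_shape=(3, 3),
        zone_layout=STUDY_LAYOUT,
        scenario="historical",
        source_kind="observed",
    )
    hist_name = f"tmax_historical.{ext}"
    write_tmax_grid(generate_grid(base_cfg), out_dir / hist_name, grid_format)

    ensemble_paths: dict[str, list[str]] = {}
    for si, scenario in enumerate(scenarios):
        cfg = replace(
            base_cfg,
            years=years_future,
            scenario=scenario,
            seed=int((seed + 104_729 * (si + 1)) % 2**31),
            n_members=n_members,
        )
        names = []
        for grid in generate_ensemble(cfg):
            name = f"tmax_{scenario}_{grid.member_id}.{ext}"
            write_tmax_grid(grid, out_dir / name, grid_format)
            names.append(name)
        ensemble_paths[scenario] = names

    cities = generate_cities(seed + 17, n_cities, base_cfg)
    write_city_table(cities, out_dir / "cities.csv")

    deaths, population = generate_mortality(seed + 29, target_ratio=target_ratio)
    deaths.to_csv(out_dir / "mortality.csv", index=False)
    population.to_csv(out_dir / "population.csv", index=False)

    config = {
        "historical_grid": hist_name,
        "city_table": "cities.csv",
        "ensemble": ensemble_paths,
        "mortality_table": "mortality.csv",
        "population_table": "population.csv",
        "baseline_window": [max(1950, years_hist[0]), 2010],
        "scenarios": list(scenarios),
        "output_dir": "out",
        "seed": seed,
    }
    cfg_path = out_dir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return cfg_path
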