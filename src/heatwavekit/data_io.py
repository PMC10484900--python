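"""Readers, writers, and per-city extraction for gridded daily Tmax.

Two grid dialects are supported:

* NetCDF with CF-style dims ``time``/``lat``/``lon`` and a variable
  named ``tmax`` or ``tasmax`` (classic format via the scipy backend);
* a long-form CSV with columns ``date,lat,lon,tmax_c`` intended for
  small toy grids.

Temperatures are stored in °C; fields read in Kelvin are converted
automatically (any physically plausible Earth Tmax in K exceeds 200,
which no Tmax in °C does). Missing values are carried as NaN.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .errors import DomainError, FormatError, ResolutionError, ValidationError
from .zones import Zone

SCENARIOS = ("historical", "SSP245", "SSP585")

_TMAX_VAR_NAMES = ("tmax", "tasmax")
_KELVIN_FLOOR = 200.0  # finite daily Tmax above this is taken to be Kelvin


@dataclass
class TemperatureGrid:
    """A daily maximum-temperature cube (time × lat × lon), in °C."""

    times: pd.DatetimeIndex
    lats: np.ndarray
    lons: np.ndarray
    tmax: np.ndarray  # shape (time, lat, lon), NaN = missing
    source_kind: str = "observed"  # observed | model
    scenario: str = "historical"
    member_id: str = ""
    resolution_deg: float = 1.0

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.tmax = np.asarray(self.tmax, dtype=float)
        if self.tmax.shape != (len(self.times), len(self.lats), len(self.lons)):
            raise FormatError(
                f"tmax shape {self.tmax.shape} does not match "
                f"(time={len(self.times)}, lat={len(self.lats)}, lon={len(self.lons)})"
            )
        if self.scenario not in SCENARIOS:
            raise ValidationError(
                f"scenario {self.scenario!r} not in {SCENARIOS}"
            )
        _check_monotone(self.lats, "lat")
        _check_monotone(self.lons, "lon")
        _check_daily(self.times)

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {"tmax": (("time", "lat", "lon"), self.tmax)},
            coords={"time": self.times, "lat": self.lats, "lon": self.lons},
            attrs={
                "source_kind": self.source_kind,
                "scenario": self.scenario,
                "member_id": self.member_id,
                "resolution_deg": self.resolution_deg,
            },
        )
        ds["tmax"].attrs["units"] = "degC"
        return ds


@dataclass(frozen=True)
class City:
    """A smart city with its homogeneous temperature zone."""

    city_id: str
    name: str
    lat: float
    lon: float
    zone: Zone
    state: str = ""

    @property
    def fixed_threshold(self) -> float:
        return self.zone.fixed_threshold


@dataclass
class CitySeries:
    """Daily Tmax for one city, extracted from a grid."""

    city: City
    dates: pd.DatetimeIndex
    tmax: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.tmax = np.asarray(self.tmax, dtype=float)
        if len(self.dates) != len(self.tmax):
            raise ValidationError("dates and tmax must have equal length")
        if self.dates.has_duplicates:
            raise ValidationError("duplicate dates in city series")


def _check_monotone(arr: np.ndarray, name: str) -> None:
    if arr.size == 0:
        raise FormatError(f"empty {name} coordinate")
    d = np.diff(arr)
    if arr.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise FormatError(f"{name} coordinate is not strictly monotone")


def _check_daily(times: pd.DatetimeIndex) -> None:
    if len(times) == 0:
        raise FormatError("empty time coordinate")
    if len(times) > 1:
        if not np.all(np.diff(times.values) == np.timedelta64(1, "D")):
            raise ResolutionError("time coordinate is not a strict daily calendar")


def _maybe_kelvin_to_c(values: np.ndarray) -> np.ndarray:
    finite = values[np.isfinite(values)]
    if finite.size and np.nanmedian(finite) > _KELVIN_FLOOR:
        return values - 273.15
    return values


def read_tmax_grid(
    path: str | Path,
    format: str | None = None,
    *,
    source_kind: str = "observed",
    scenario: str = "historical",
    member_id: str = "",
) -> TemperatureGrid:
    """Read a daily Tmax grid from NetCDF or long-form CSV.

    ``format`` is inferred from the suffix when omitted. Kelvin fields
    are converted to °C; missing values are preserved as NaN.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "netcdf"
    if format == "netcdf":
        return _read_netcdf(path, source_kind, scenario, member_id)
    if format == "csv":
        return _read_csv_grid(path, source_kind, scenario, member_id)
    raise ValueError(f"unknown grid format {format!r}")


def _read_netcdf(path: Path, source_kind: str, scenario: str, member_id: str) -> TemperatureGrid:
    with xr.open_dataset(path) as ds:
        for dim in ("time", "lat", "lon"):
            if dim not in ds.coords and dim not in ds.dims:
                raise FormatError(f"missing coordinate variable {dim!r} in {path}")
        var = next((v for v in _TMAX_VAR_NAMES if v in ds.data_vars), None)
        if var is None:
            raise FormatError(
                f"no Tmax variable ({'/'.join(_TMAX_VAR_NAMES)}) in {path}"
            )
        da = ds[var].transpose("time", "lat", "lon")
        values = _maybe_kelvin_to_c(da.values.astype(float))
        attrs = ds.attrs
        return TemperatureGrid(
            times=pd.DatetimeIndex(ds["time"].values),
            lats=ds["lat"].values,
            lons=ds["lon"].values,
            tmax=values,
            source_kind=str(attrs.get("source_kind", source_kind)),
            scenario=str(attrs.get("scenario", scenario)),
            member_id=str(attrs.get("member_id", member_id)),
            resolution_deg=float(attrs.get("resolution_deg", _infer_resolution(ds["lat"].values))),
        )


def _read_csv_grid(path: Path, source_kind: str, scenario: str, member_id: str) -> TemperatureGrid:
    df = pd.read_csv(path)
    required = {"date", "lat", "lon", "tmax_c"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"CSV grid {path} must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    df["date"] = pd.to_datetime(df["date"])
    times = pd.DatetimeIndex(np.sort(df["date"].unique()))
    lats = np.sort(df["lat"].unique())
    lons = np.sort(df["lon"].unique())
    cube = np.full((len(times), len(lats), len(lons)), np.nan)
    ti = pd.Series(np.arange(len(times)), index=times)
    yi = pd.Series(np.arange(len(lats)), index=lats)
    xi = pd.Series(np.arange(len(lons)), index=lons)
    cube[
        ti[df["date"]].to_numpy(),
        yi[df["lat"]].to_numpy(),
        xi[df["lon"]].to_numpy(),
    ] = df["tmax_c"].to_numpy(dtype=float)
    cube = _maybe_kelvin_to_c(cube)
    return TemperatureGrid(
        times=times,
        lats=lats,
        lons=lons,
        tmax=cube,
        source_kind=source_kind,
        scenario=scenario,
        member_id=member_id,
        resolution_deg=_infer_resolution(lats),
    )


def _infer_resolution(lats: np.ndarray) -> float:
    lats = np.asarray(lats, dtype=float)
    if lats.size < 2:
        return 1.0
    return float(np.abs(np.diff(lats)).min())


def write_tmax_grid(grid: TemperatureGrid, path: str | Path, format: str | None = None) -> None:
    """Write a grid in the same dialect :func:`read_tmax_grid` accepts."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "netcdf"
    if format == "netcdf":
        grid.to_dataset().to_netcdf(path, engine="scipy")
    elif format == "csv":
        t, y, x = np.meshgrid(
            np.arange(len(grid.times)),
            np.arange(len(grid.lats)),
            np.arange(len(grid.lons)),
            indexing="ij",
        )
        df = pd.DataFrame(
            {
                "date": grid.times[t.ravel()].strftime("%Y-%m-%d"),
                "lat": grid.lats[y.ravel()],
                "lon": grid.lons[x.ravel()],
                "tmax_c": grid.tmax.ravel(),
            }
        )
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown grid format {format!r}")


def nearest_cell_index(grid: TemperatureGrid, lat: float, lon: float) -> tuple[int, int]:
    """Index of the grid cell nearest to (lat, lon), Euclidean in degrees.

    Ties resolve to the lower (lat, lon) index, in that priority order.
    """
    d2 = (grid.lats[:, None] - lat) ** 2 + (grid.lons[None, :] - lon) ** 2
    flat = int(np.argmin(d2))  # first occurrence = lowest (lat, lon) index
    return flat // len(grid.lons), flat % len(grid.lons)


def extract_city_series(grid: TemperatureGrid, city: City) -> CitySeries:
    """Take a city's daily series from the nearest grid cell."""
    lat_lo, lat_hi = sorted((grid.lats[0], grid.lats[-1]))
    lon_lo, lon_hi = sorted((grid.lons[0], grid.lons[-1]))
    half = grid.resolution_deg / 2.0
    if not (lat_lo - half <= city.lat <= lat_hi + half) or not (
        lon_lo - half <= city.lon <= lon_hi + half
    ):
        raise DomainError(
            f"city {city.city_id} at ({city.lat}, {city.lon}) is outside the "
            f"grid domain [{lat_lo}, {lat_hi}] × [{lon_lo}, {lon_hi}]"
        )
    iy, ix = nearest_cell_index(grid, city.lat, city.lon)
    return CitySeries(
        city=city,
        dates=grid.times,
        tmax=grid.tmax[:, iy, ix].copy(),
        provenance=(
            f"{grid.source_kind}/{grid.scenario}"
            f"{'/' + grid.member_id if grid.member_id else ''}"
            f"; nearest-cell (lat={grid.lats[iy]:g}, lon={grid.lons[ix]:g})"
        ),
    )


CITY_COLUMNS = ["city_id", "name", "lat", "lon", "zone", "state"]


def read_city_table(path: str | Path) -> list[City]:
    """Read the city table CSV, validating zone labels."""
    df = pd.read_csv(
        path,
        dtype={"city_id": str, "name": str, "state": str},
        float_precision="round_trip",
    )
    missing = [c for c in CITY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"city table {path} missing columns {missing}")
    cities = []
    for row in df.itertuples(index=False):
        try:
            zone = Zone.from_label(str(row.zone))
        except ValueError as exc:
            raise ValidationError(str(exc)) from exc
        cities.append(
            City(
                city_id=str(row.city_id),
                name=str(row.name),
                lat=float(row.lat),
                lon=float(row.lon),
                zone=zone,
                state=str(row.state),
            )
        )
    return cities


def write_city_table(cities: Sequence[City], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CITY_COLUMNS)
        for c in cities:
            w.writerow([c.city_id, c.name, repr(c.lat), repr(c.lon), c.zone.value, c.state])


def write_stats_table(records: Iterable[dict], path: str | Path) -> None:
    """Write a list of record dicts as CSV with an explicit header."""
    records = list(records)
    if not records:
        raise ValidationError("refusing to write an empty stats table")
    pd.DataFrame.from_records(records).to_csv(path, index=False)
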