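"""Shared fixtures: tiny cities, series builders, and a study directory."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from heatwavekit.data_io import City, CitySeries
from heatwavekit.zones import Zone


@pytest.fixture
def plains_city() -> City:
    return City("nc01", "Plainsville", 25.0, 80.0, Zone.NORTH_CENTRAL, "StateA")


@pytest.fixture
def coast_city() -> City:
    return City("wc01", "Coastburg", 10.0, 76.0, Zone.WEST_COAST, "StateB")


def make_series(city: City, year: int, amj_tmax: np.ndarray) -> CitySeries:
    """A CitySeries covering exactly one Apr 1 – Jun 30 window."""
    dates = pd.date_range(f"{year}-04-01", f"{year}-06-30", freq="D")
    assert len(dates) == len(amj_tmax)
    return CitySeries(city=city, dates=dates, tmax=np.asarray(amj_tmax, float))


def constant_series(city: City, years: tuple[int, int], value: float) -> CitySeries:
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[1]}-12-31", freq="D")
    return CitySeries(city=city, dates=dates, tmax=np.full(len(dates), value))


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """A small complete synthetic study written once per session."""
    from heatwavekit.synthetic_data import write_study

    root = tmp_path_factory.mktemp("study")
    cfg_path = write_study(
        7, root, n_members=2, n_cities=6, years_future=(2021, 2098)
    )
    return cfg_path
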