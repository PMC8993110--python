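"""Synthetic satellite-record generator with known ground truth.

Emulates the statistical structure of city-scale column records in the
tropics — a linear relative trend on a positive baseline, one annual
seasonal harmonic, burning-season enhancements confined to a prescribed
set of calendar months, pixel-level sampling with cloud-gap months — plus
compounding demographics. Every stochastic operation is driven by a single
integer seed, and identical seeds give bit-identical output.

Ground truth is exposed (:func:`monthly_truth`) so downstream trend fits,
source partitions and exposure/mortality estimates can be tested by
parameter recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .geometry import EmptyRegionError, RegionGeometry

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class SyntheticScenario:
    """Truth model for one synthetic city record.

    The noise-free monthly-mean column at time ``t`` years from record start
    (``t = month_index / 12``) is::

        baseline * (1 + rel_trend * t
                      + seasonal_amplitude * sin(2*pi*t + phase)
                      + bb_excess * (1 + bb_trend * t) * [month in bb_months])

    Gaussian noise with standard deviation ``noise_sd * baseline`` is added
    to the monthly mean; pixel scatter within a month averages out exactly,
    so with ``noise_sd = 0`` the sampled monthly mean equals the truth to
    machine precision.
    """

    baseline_column: float = 1.0
    rel_trend: float = 0.03            # fraction per year
    seasonal_amplitude: float = 0.15   # fraction of baseline
    seasonal_phase: float = 0.0        # months
    bb_months: frozenset[int] = frozenset()
    bb_excess: float = 0.0             # fraction of baseline in bb months
    bb_trend: float = 0.0              # fraction per year applied to bb_excess
    noise_sd: float = 0.0              # fraction of baseline
    gap_prob: float = 0.0              # P(month has < 5 usable pixels)
    pixel_size_km: float = 6.5
    years: tuple[int, int] = (2005, 2018)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_column <= 0:
            raise ValueError("baseline_column must be > 0")
        if not 0.0 <= self.gap_prob < 1.0:
            raise ValueError("gap_prob must lie in [0, 1)")
        if not set(self.bb_months) <= set(range(1, 13)):
            raise ValueError("bb_months must be a subset of {1..12}")
        if self.years[1] < self.years[0] + 1:
            raise ValueError("record must span at least 2 years")

    @property
    def n_months(self) -> int:
        return 12 * (self.years[1] - self.years[0] + 1)

    def month_index(self) -> pd.DataFrame:
        """Calendar frame: year, month, and t in years from record start."""
        idx = np.arange(self.n_months)
        return pd.DataFrame(
            {
                "year": self.years[0] + idx // 12,
                "month": 1 + idx % 12,
                "t": idx / 12.0,
            }
        )


@dataclass(frozen=True)
class DemographicScenario:
    """Truth model for one city's demographics and PM2.5 anchor.

    Age structure is collapsed to a single >=14-year stratum with one
    all-cause baseline mortality rate per year (deaths per person per year).
    """

    pop_start: float = 1.0e6
    pop_growth: float = 0.02           # fraction per year, compounding
    frac_over14: float = 0.7
    y0_by_year: dict[int, float] = field(default_factory=dict)
    y0_default: float = 0.008
    anchor_pm25: float = 35.0          # ug m-3 at anchor_year
    anchor_year: int = 2012

    def __post_init__(self) -> None:
        if self.pop_start <= 0:
            raise ValueError("pop_start must be > 0")
        if not 0.0 < self.frac_over14 <= 1.0:
            raise ValueError("frac_over14 must lie in (0, 1]")
        if any(v < 0 for v in self.y0_by_year.values()) or self.y0_default < 0:
            raise ValueError("baseline mortality rates must be >= 0")


def monthly_truth(scenario: SyntheticScenario) -> pd.DataFrame:
    """Noise-free monthly-mean series implied by the scenario.

    Columns: year, month, t, mean.
    """
    frame = scenario.month_index()
    t = frame["t"].to_numpy()
    phase = TWO_PI * scenario.seasonal_phase / 12.0
    signal = 1.0 + scenario.rel_trend * t
    signal = signal + scenario.seasonal_amplitude * np.sin(TWO_PI * t + phase)
    in_bb = frame["month"].isin(list(scenario.bb_months)).to_numpy()
    signal = signal + np.where(
        in_bb, scenario.bb_excess * (1.0 + scenario.bb_trend * t), 0.0
    )
    frame["mean"] = scenario.baseline_column * signal
    return frame


def monthly_means(scenario: SyntheticScenario, rng: np.random.Generator | None = None):
    """Monthly means with additive noise, plus the gap-month mask."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    frame = monthly_truth(scenario)
    if scenario.noise_sd > 0:
        frame["mean"] += rng.normal(
            0.0, scenario.noise_sd * scenario.baseline_column, len(frame)
        )
    frame["gap"] = rng.random(len(frame)) < scenario.gap_prob
    return frame


def _points_in_polygon(rng, region: RegionGeometry, n: int):
    """Rejection-sample n points uniformly inside the region polygon."""
    minx, miny, maxx, maxy = region.polygon.bounds
    lons = np.empty(n)
    lats = np.empty(n)
    got = 0
    while got < n:
        m = max(4 * (n - got), 16)
        cand_x = rng.uniform(minx, maxx, m)
        cand_y = rng.uniform(miny, maxy, m)
        ok = region.contains(cand_x, cand_y)
        take = min(int(ok.sum()), n - got)
        lons[got : got + take] = cand_x[ok][:take]
        lats[got : got + take] = cand_y[ok][:take]
        got += take
    return lons, lats


def generate_pixels(
    scenario: SyntheticScenario,
    city: RegionGeometry,
    pixels_per_month: tuple[int, int] = (8, 15),
    pixel_scatter: float = 0.1,
    qa_fail_prob: float = 0.05,
) -> pd.DataFrame:
    """Pixel-level observation table for one region.

    Each non-gap month emits between ``pixels_per_month`` usable pixels whose
    centres fall inside the (unbuffered) region polygon and whose values
    average exactly to that month's mean — pixel scatter is mean-centred so
    city-wide sampling reproduces the scenario truth. Gap months emit fewer
    than 5 usable pixels. A small fraction of extra pixels carry
    ``qa_pass = False`` (and perturbed values) to exercise QA filtering.

    Returns a table with columns lon, lat, time (ISO-8601 timestamp),
    value, qa_pass.
    """
    if city.polygon.is_empty:
        raise EmptyRegionError(f"region {city.region_id!r} has an empty geometry")
    rng = np.random.default_rng(scenario.seed)
    frame = monthly_means(scenario, rng)
    lo, hi = pixels_per_month
    rows = []
    for rec in frame.itertuples(index=False):
        n_good = int(rng.integers(0, 5)) if rec.gap else int(rng.integers(lo, hi + 1))
        n_bad = int(rng.random() < qa_fail_prob)
        n = n_good + n_bad
        if n == 0:
            continue
        lons, lats = _points_in_polygon(rng, city, n)
        scatter = rng.normal(0.0, pixel_scatter * scenario.baseline_column, n_good)
        if n_good > 0:
            scatter -= scatter.mean()      # within-month mean is exact
        values = np.concatenate(
            [rec.mean + scatter, rec.mean * (1.0 + rng.normal(0, 0.5, n_bad))]
        )
        qa = np.concatenate([np.ones(n_good, bool), np.zeros(n_bad, bool)])
        stamp = pd.Timestamp(year=int(rec.year), month=int(rec.month), day=15)
        for i in range(n):
            rows.append((lons[i], lats[i], stamp, values[i], bool(qa[i])))
    out = pd.DataFrame(rows, columns=["lon", "lat", "time", "value", "qa_pass"])
    return out


def generate_demographics(scenario: DemographicScenario, years) -> pd.DataFrame:
    """Annual demographic table: population compounds at ``pop_growth``.

    Columns: year, population, frac_over14, y0.
    """
    years = list(years)
    pop = scenario.pop_start * (1.0 + scenario.pop_growth) ** (
        np.asarray(years) - years[0]
    )
    y0 = [scenario.y0_by_year.get(y, scenario.y0_default) for y in years]
    return pd.DataFrame(
        {
            "year": years,
            "population": pop,
            "frac_over14": scenario.frac_over14,
            "y0": y0,
        }
    )


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid (cell centres) for gridded annual fields."""

    lon_min: float
    lat_min: float
    nlon: int
    nlat: int
    dlon: float = 0.25
    dlat: float = 0.25

    @property
    def lons(self) -> np.ndarray:
        return self.lon_min + self.dlon * (np.arange(self.nlon) + 0.5)

    @property
    def lats(self) -> np.ndarray:
        return self.lat_min + self.dlat * (np.arange(self.nlat) + 0.5)


def generate_burned_fraction(
    scenario: SyntheticScenario,
    grid: GridSpec,
    base_fraction: float = 0.05,
    spatial_cv: float = 0.2,
) -> xr.DataArray:
    """Gridded annual burned-fraction field consistent with the scenario.

    The field is zero everywhere when ``bb_excess`` is 0; otherwise each
    year's city-mean burned fraction scales as ``1 + bb_trend * t`` so the
    annual trend over the city has the sign of ``bb_trend``. A fixed
    (seeded) multiplicative spatial pattern adds realism without noise in
    the temporal direction.
    """
    years = np.arange(scenario.years[0], scenario.years[1] + 1)
    rng = np.random.default_rng(scenario.seed + 1)
    pattern = np.clip(
        1.0 + spatial_cv * rng.standard_normal((grid.nlat, grid.nlon)), 0.1, None
    )
    t = (years - years[0]).astype(float)
    if scenario.bb_excess == 0:
        data = np.zeros((len(years), grid.nlat, grid.nlon))
    else:
        scale = base_fraction * np.clip(1.0 + scenario.bb_trend * t, 0.0, None)
        data = scale[:, None, None] * pattern[None, :, :]
    return xr.DataArray(
        data,
        coords={"year": years, "lat": grid.lats, "lon": grid.lons},
        dims=("year", "lat", "lon"),
        name="burned_fraction",
    )


def gridded_field_to_csv(field: xr.DataArray, path) -> None:
    """Serialize a (year, lat, lon) field as tidy CSV."""
    field.to_dataframe().reset_index().to_csv(path, index=False)


def gridded_field_from_csv(path, name: str = "burned_fraction") -> xr.DataArray:
    """Read a tidy CSV back into a (year, lat, lon) DataArray."""
    df = pd.read_csv(path)
    return df.set_index(["year", "lat", "lon"])[name].to_xarray()
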