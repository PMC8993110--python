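"""City-wide monthly-mean series from pixel-level column observations.

A pixel contributes to a month's unweighted mean iff it passed QA upstream
(``qa_pass``) and its footprint centre lies inside the region polygon
dilated by the instrument buffer. Months with fewer than 5 usable pixels
are kept in the series but flagged ``retained = False`` and never enter any
fit. The point-in-domain test is inclusive of the boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .geometry import (
    RegionGeometry,
    destination_point,
    haversine_km,
    square_region,
)

logger = logging.getLogger(__name__)

MIN_PIXELS_PER_MONTH = 5

PIXEL_COLUMNS = ["lon", "lat", "time", "value", "qa_pass"]


@dataclass
class MonthlyCitySeries:
    """City-wide monthly-mean time series.

    ``data`` has one row per calendar month of the record span, columns
    ``year, month, mean, n_pixels, retained`` (mean is NaN where no usable
    pixel fell in the month; it is never imputed as zero). Species is one of
    NO2, HCHO, HCHO_reactive, NH3, AOD.
    """

    region_id: str
    species: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        periods = self.periods()
        if periods.duplicated().any():
            raise ValueError("duplicate months in series")
        if not periods.is_monotonic_increasing:
            raise ValueError("months must be strictly increasing")

    def periods(self) -> pd.PeriodIndex:
        return pd.PeriodIndex(
            pd.to_datetime(
                {"year": self.data["year"], "month": self.data["month"], "day": 1}
            ),
            freq="M",
        )

    @property
    def months_in_record(self) -> int:
        return len(self.data)

    @property
    def n_retained(self) -> int:
        return int(self.data["retained"].sum())

    def retained(self) -> pd.DataFrame:
        """Rows entering downstream fits, with t in years from record start."""
        out = self.data[self.data["retained"]].copy()
        start = self.periods()[0]
        out["t"] = [(p - start).n / 12.0 for p in self.periods()[self.data["retained"].to_numpy()]]
        return out

    def t_years(self) -> np.ndarray:
        """Time of every month in years from record start."""
        start = self.periods()[0]
        return np.array([(p - start).n / 12.0 for p in self.periods()])

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "species", self.species)
        out.insert(0, "region_id", self.region_id)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MonthlyCitySeries":
        df = pd.read_csv(path)
        return cls(
            region_id=str(df["region_id"].iloc[0]),
            species=str(df["species"].iloc[0]),
            data=df.drop(columns=["region_id", "species"]).reset_index(drop=True),
        )


def _monthly_aggregate(pixels: pd.DataFrame, record_span) -> pd.DataFrame:
    """Group usable pixels by calendar month (UTC) over the record span."""
    times = pd.to_datetime(pixels["time"])
    per = times.dt.to_period("M")
    grouped = pixels.groupby(per)["value"].agg(["mean", "size"])
    if record_span is None:
        if grouped.empty:
            raise ValueError("cannot infer record span from an empty pixel set")
        start, end = grouped.index.min(), grouped.index.max()
    else:
        start, end = (pd.Period(p, freq="M") for p in record_span)
    full = pd.period_range(start, end, freq="M")
    grouped = grouped.reindex(full)
    n = grouped["size"].fillna(0).astype(int)
    out = pd.DataFrame(
        {
            "year": full.year,
            "month": full.month,
            "mean": grouped["mean"].to_numpy(),
            "n_pixels": n.to_numpy(),
            "retained": (n >= MIN_PIXELS_PER_MONTH).to_numpy(),
        }
    )
    # a month below the pixel threshold keeps its mean for inspection but is
    # excluded from every fit via retained=False
    return out


def sample_region(
    pixels: pd.DataFrame,
    region: RegionGeometry,
    species: str,
    record_span=None,
) -> MonthlyCitySeries:
    """City-wide monthly means by sampling pixel centres within the domain.

    Parameters
    ----------
    pixels:
        Table with columns lon, lat, time, value, qa_pass.
    region:
        Sampling domain; its ``buffer_km`` dilation is applied.
    species:
        Label carried through to outputs.
    record_span:
        Optional (start, end) months defining the record; inferred from the
        retained pixels when omitted.
    """
    ok = pixels["qa_pass"].to_numpy(bool)
    inside = np.zeros(len(pixels), bool)
    if ok.any():
        inside[ok] = region.contains(
            pixels.loc[ok, "lon"].to_numpy(), pixels.loc[ok, "lat"].to_numpy()
        )
    usable = pixels[inside]
    if usable.empty and record_span is None:
        warnings.warn(
            f"no usable pixels for region {region.region_id!r}; empty series"
        )
        data = pd.DataFrame(
            columns=["year", "month", "mean", "n_pixels", "retained"]
        ).astype({"year": int, "month": int, "n_pixels": int, "retained": bool})
        return MonthlyCitySeries(region.region_id, species, data)
    data = _monthly_aggregate(usable, record_span)
    if not data["retained"].any():
        warnings.warn(
            f"region {region.region_id!r}: zero retained months "
            f"(all below {MIN_PIXELS_PER_MONTH} pixels)"
        )
    return MonthlyCitySeries(region.region_id, species, data)


def background_series(
    pixels: pd.DataFrame,
    ocean_region: RegionGeometry,
    species: str = "HCHO",
    paired_city: RegionGeometry | None = None,
    lat_tolerance_deg: float = 1.0,
    record_span=None,
) -> MonthlyCitySeries:
    """Monthly mean background columns over a remote ocean domain.

    The ocean domain should span the same latitude range as its paired city
    so background seasonality matches; a mismatch beyond
    ``lat_tolerance_deg`` is logged as a warning, not an error.
    """
    if ocean_region.kind != "ocean_background":
        raise ValueError("ocean_region.kind must be 'ocean_background'")
    if paired_city is not None:
        _, miny_o, _, maxy_o = ocean_region.polygon.bounds
        _, miny_c, _, maxy_c = paired_city.polygon.bounds
        if (
            abs(miny_o - miny_c) > lat_tolerance_deg
            or abs(maxy_o - maxy_c) > lat_tolerance_deg
        ):
            logger.warning(
                "ocean background %s latitude range [%.2f, %.2f] mismatches "
                "city %s [%.2f, %.2f] beyond %.1f deg",
                ocean_region.region_id, miny_o, maxy_o,
                paired_city.region_id, miny_c, maxy_c, lat_tolerance_deg,
            )
    return sample_region(pixels, ocean_region, species, record_span=record_span)


def subtract_background(
    city: MonthlyCitySeries,
    background: MonthlyCitySeries,
    fit,
) -> MonthlyCitySeries:
    """Reactive-component series: city means minus the fitted background.

    ``fit`` is the seasonal-trend fit of the ocean background series; its
    fitted value (not the raw background mean) is subtracted month by month,
    which removes the slowly varying methane-oxidation background while
    keeping city months that the background record happens to miss. Negative
    residuals — expected when the column is near the detection limit — are
    retained and flagged.
    """
    if fit.region_id != background.region_id:
        raise ValueError("fit was not produced from the given background series")
    start, end = fit.record_start, fit.record_end
    periods = city.periods()
    if len(periods) and (periods[0] < start or periods[-1] > end):
        raise ValueError(
            f"city record {periods[0]}..{periods[-1]} extends outside the "
            f"background fit support {start}..{end}"
        )
    fitted = fit.predict_months(periods)
    data = city.data.copy()
    data["mean"] = data["mean"].to_numpy() - fitted
    data["negative"] = data["mean"] < 0
    n_neg = int((data["negative"] & data["retained"]).sum())
    if n_neg:
        logger.warning(
            "region %s: %d retained months with negative reactive residual "
            "(column near detection limit); values kept and flagged",
            city.region_id, n_neg,
        )
    return MonthlyCitySeries(city.region_id, f"{city.species}_reactive", data)


def rural_reference(
    pixels: pd.DataFrame,
    city_center: tuple[float, float],
    bearing_deg: float = 90.0,
    distance_km: float = 75.0,
    box_size_deg: float = 0.2,
    species: str = "HCHO",
    record_span=None,
) -> MonthlyCitySeries:
    """Series over a rural box 50–100 km from the city centre.

    Used to check that biogenic VOCs (isoprene-dominated rural HCHO) do not
    drive the city trend. The box centre is placed at ``distance_km`` along
    ``bearing_deg`` from the city centroid; distances outside [50, 100] km
    are rejected.
    """
    if not 50.0 <= distance_km <= 100.0:
        raise ValueError(
            f"rural reference box must lie 50-100 km from the city; "
            f"got {distance_km} km"
        )
    lon, lat = destination_point(
        city_center[0], city_center[1], bearing_deg, distance_km
    )
    box = square_region(
        "rural_reference", lon, lat, box_size_deg, kind="rural_reference"
    )
    d = haversine_km(city_center[0], city_center[1], lon, lat)
    assert 50.0 <= round(d, 6) <= 100.0
    return sample_region(pixels, box, species, record_span=record_span)


def sample_gridded_annual_field(
    field: xr.DataArray,
    region: RegionGeometry,
    mode: str = "mean",
) -> pd.Series:
    """Annual series over a region from a gridded annual field.

    Grid cells are weighted by the fraction of their area overlapping the
    region's (buffered) sampling extent. ``mode='mean'`` gives the
    area-weighted mean (burned fraction); ``mode='sum'`` attributes each
    cell's value in proportion to its overlap and sums (emissions).
    """
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    import shapely

    lats = field["lat"].to_numpy()
    lons = field["lon"].to_numpy()
    dlat = float(np.diff(lats).mean()) if len(lats) > 1 else 1.0
    dlon = float(np.diff(lons).mean()) if len(lons) > 1 else 1.0
    lon_g, lat_g = np.meshgrid(lons, lats)
    cells = shapely.box(
        (lon_g - dlon / 2).ravel(),
        (lat_g - dlat / 2).ravel(),
        (lon_g + dlon / 2).ravel(),
        (lat_g + dlat / 2).ravel(),
    )
    domain = region.sampling_polygon()
    inter = shapely.area(shapely.intersection(cells, domain))
    frac = (inter / shapely.area(cells)).reshape(len(lats), len(lons))
    if frac.sum() == 0:
        raise ValueError(
            f"region {region.region_id!r} does not overlap the gridded field"
        )
    # cos(lat) converts degree-cell overlap fractions to true-area weights
    area_w = frac * np.cos(np.radians(lat_g))
    values = field.transpose("year", "lat", "lon").to_numpy()
    if mode == "mean":
        out = (values * area_w).sum(axis=(1, 2)) / area_w.sum()
    else:
        out = (values * frac).sum(axis=(1, 2))
    return pd.Series(out, index=pd.Index(field["year"].to_numpy(), name="year"))
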