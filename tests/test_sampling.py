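import logging

import numpy as np
import pandas as pd
import pytest

from citytrends import (
    background_series,
    fit_seasonal_trend,
    rural_reference,
    sample_gridded_annual_field,
    sample_region,
    square_region,
    subtract_background,
)
from citytrends.geometry import haversine_km
from conftest import make_series

import xarray as xr


def pixel_table(lons, lats, values, month="2005-06", qa=True):
    n = len(values)
    stamp = pd.Period(month, "M").to_timestamp() + pd.Timedelta(days=14)
    return pd.DataFrame(
        {
            "lon": lons if hasattr(lons, "__len__") else [lons] * n,
            "lat": lats if hasattr(lats, "__len__") else [lats] * n,
            "time": [stamp] * n,
            "value": values,
            "qa_pass": qa if hasattr(qa, "__len__") else [qa] * n,
        }
    )


class TestSampleRegion:
    def test_five_pixel_month_mean_and_retention(self, unbuffered_region):
        pixels = pixel_table(10.0, 5.0, [1, 2, 3, 4, 5])
        series = sample_region(pixels, unbuffered_region, "NO2")
        row = series.data.iloc[0]
        assert row["mean"] == 3.0
        assert row["n_pixels"] == 5
        assert bool(row["retained"])

    def test_four_pixel_month_present_but_not_retained(self, unbuffered_region):
        pixels = pixel_table(10.0, 5.0, [1, 2, 3, 4])
        with pytest.warns(UserWarning, match="zero retained"):
            series = sample_region(pixels, unbuffered_region, "NO2")
        row = series.data.iloc[0]
        assert row["n_pixels"] == 4
        assert not bool(row["retained"])
        assert row["mean"] == 2.5  # mean still reported for inspection

    def test_qa_failed_pixels_never_enter_the_mean(self, unbuffered_region):
        pixels = pixel_table(10.0, 5.0, [1, 2, 3, 4, 5, 999],
                             qa=[True] * 5 + [False])
        series = sample_region(pixels, unbuffered_region, "NO2")
        assert series.data["mean"].iloc[0] == 3.0

    def test_boundary_pixel_counts_as_inside(self):
        region = square_region("sq", 0.0, 0.0, 1.0, buffer_km=0.0)
        pixels = pixel_table([0.5] * 5, [0.0] * 5, [2.0] * 5)  # on the edge
        series = sample_region(pixels, region, "NO2")
        assert series.data["n_pixels"].iloc[0] == 5

    def test_permutation_invariance(self, city_region):
        rng = np.random.default_rng(0)
        lons = rng.uniform(9.7, 10.3, 40)
        lats = rng.uniform(4.7, 5.3, 40)
        vals = rng.normal(5, 1, 40)
        pixels = pixel_table(lons, lats, vals)
        shuffled = pixels.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = sample_region(pixels, city_region, "NO2")
        b = sample_region(shuffled, city_region, "NO2")
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_matches_brute_force_point_in_polygon_loop(self):
        # square domain: the oracle is an inclusive coordinate comparison
        region = square_region("sq", 10.0, 5.0, 0.4, buffer_km=0.0)
        rng = np.random.default_rng(2)
        n = 1000
        lons = rng.uniform(9.6, 10.4, n)
        lats = rng.uniform(4.6, 5.4, n)
        vals = rng.normal(3, 1, n)
        pixels = pixel_table(lons, lats, vals)
        inside = [
            abs(lon - 10.0) <= 0.2 and abs(lat - 5.0) <= 0.2
            for lon, lat in zip(lons, lats)
        ]
        expected = vals[np.array(inside)]
        series = sample_region(pixels, region, "NO2")
        assert series.data["n_pixels"].iloc[0] == len(expected)
        assert series.data["mean"].iloc[0] == pytest.approx(expected.mean(), rel=1e-12)

    def test_enlarging_buffer_never_loses_pixels(self):
        rng = np.random.default_rng(3)
        pixels = pixel_table(
            rng.uniform(9.5, 10.5, 200), rng.uniform(4.5, 5.5, 200),
            rng.normal(1, 0.1, 200),
        )
        counts = []
        for buf in (0.0, 5.0, 10.0, 25.0):
            region = square_region("sq", 10.0, 5.0, 0.3, buffer_km=buf)
            counts.append(sample_region(pixels, region, "NO2").data["n_pixels"].iloc[0])
        assert counts == sorted(counts)

    def test_zero_usable_pixels_warns_not_fails(self, unbuffered_region):
        pixels = pixel_table(10.0, 5.0, [1.0] * 3, qa=False)
        with pytest.warns(UserWarning, match="no usable pixels"):
            series = sample_region(pixels, unbuffered_region, "NO2")
        assert series.data.empty


class TestBackground:
    ocean = square_region("ocean", -5.0, 5.0, 0.3, kind="ocean_background")

    def test_constant_ocean_field_reproduced(self):
        frames = [
            pixel_table([-5.0] * 6, [5.0] * 6, [4.2] * 6, month=f"2005-{m:02d}")
            for m in range(1, 13)
        ]
        series = background_series(pd.concat(frames), self.ocean)
        np.testing.assert_allclose(series.data["mean"], 4.2)

    def test_kind_enforced(self, city_region):
        with pytest.raises(ValueError, match="ocean_background"):
            background_series(pixel_table(10.0, 5.0, [1.0] * 5), city_region)

    def test_latitude_mismatch_logged(self, caplog):
        far_city = square_region("north", -5.0, 30.0, 0.3)
        pixels = pixel_table([-5.0] * 5, [5.0] * 5, [1.0] * 5)
        with caplog.at_level(logging.WARNING, logger="citytrends.sampling"):
            background_series(pixels, self.ocean, paired_city=far_city)
        assert any("latitude range" in r.message for r in caplog.records)


class TestSubtractBackground:
    def _bg_fit(self, values, region_id="ocean"):
        bg = make_series(values, region_id=region_id, species="HCHO")
        return bg, fit_seasonal_trend(bg)

    def test_city_equal_to_background_gives_near_zero_residual(self):
        t = np.arange(48) / 12.0
        vals = 5.0 + 0.1 * t + 0.5 * np.sin(2 * np.pi * t)
        bg, fit = self._bg_fit(vals)
        city = make_series(vals, region_id="c", species="HCHO")
        residual = subtract_background(city, bg, fit)
        np.testing.assert_allclose(residual.data["mean"], 0.0, atol=1e-9)
        assert residual.species == "HCHO_reactive"

    def test_additive_offset_recovered(self):
        t = np.arange(48) / 12.0
        vals = 5.0 + 0.5 * np.sin(2 * np.pi * t)
        bg, fit = self._bg_fit(vals)
        city = make_series(vals + 1.7, region_id="c", species="HCHO")
        residual = subtract_background(city, bg, fit)
        np.testing.assert_allclose(residual.data["mean"], 1.7, atol=1e-9)

    def test_negative_residuals_kept_and_flagged(self, caplog):
        bg, fit = self._bg_fit([5.0] * 48)
        city = make_series([4.5] * 48, region_id="c", species="HCHO")
        with caplog.at_level(logging.WARNING, logger="citytrends.sampling"):
            residual = subtract_background(city, bg, fit)
        assert (residual.data["mean"] < 0).all()
        assert residual.data["negative"].all()
        assert any("negative" in r.message for r in caplog.records)

    def test_months_outside_fit_support_error(self):
        bg, fit = self._bg_fit([5.0] * 48)
        city = make_series([5.0] * 60, region_id="c", species="HCHO")
        with pytest.raises(ValueError, match="outside"):
            subtract_background(city, bg, fit)

    def test_fit_must_come_from_the_background_series(self):
        bg, fit = self._bg_fit([5.0] * 48)
        other = make_series([5.0] * 48, region_id="elsewhere", species="HCHO")
        with pytest.raises(ValueError, match="not produced"):
            subtract_background(make_series([5.0] * 48), other, fit)


class TestRuralReference:
    center = (36.8, -1.3)

    def _pixels_at(self, distance_km, bearing=90.0):
        from citytrends.geometry import destination_point

        lon, lat = destination_point(*self.center, bearing, distance_km)
        return pixel_table([lon] * 5, [lat] * 5, [2.0] * 5)

    def test_box_at_75_km_accepted(self):
        series = rural_reference(self._pixels_at(75.0), self.center,
                                 bearing_deg=90.0, distance_km=75.0)
        assert series.data["n_pixels"].iloc[0] == 5

    def test_box_at_30_km_rejected(self):
        with pytest.raises(ValueError, match="50-100"):
            rural_reference(self._pixels_at(30.0), self.center, distance_km=30.0)

    def test_box_size_is_exact(self):
        from citytrends.geometry import destination_point, square_region

        lon, lat = destination_point(*self.center, 90.0, 75.0)
        box = square_region("rural_reference", lon, lat, 0.2)
        minx, miny, maxx, maxy = box.polygon.bounds
        assert maxx - minx == pytest.approx(0.2, abs=1e-12)
        assert maxy - miny == pytest.approx(0.2, abs=1e-12)
        assert 50.0 <= haversine_km(*self.center, lon, lat) <= 100.0


class TestGriddedField:
    def _field(self, values, lons, lats, years=(2005,)):
        data = np.broadcast_to(
            np.asarray(values, float), (len(years), len(lats), len(lons))
        ).copy()
        return xr.DataArray(
            data,
            coords={"year": list(years), "lat": list(lats), "lon": list(lons)},
            dims=("year", "lat", "lon"),
        )

    def test_uniform_field_mean(self, unbuffered_region):
        field = self._field(0.7, lons=[9.9, 10.1], lats=[4.9, 5.1])
        annual = sample_gridded_annual_field(field, unbuffered_region, mode="mean")
        assert annual.iloc[0] == pytest.approx(0.7, rel=1e-12)

    def test_two_equal_area_cells_mean_and_sum(self):
        # region covers both 1-deg cells exactly; cells at the same latitude
        region = square_region("sq", 10.0, 0.0, 2.0, buffer_km=0.0)
        field = self._field([[2.0, 4.0]], lons=[9.5, 10.5], lats=[0.0])
        mean = sample_gridded_annual_field(field, region, mode="mean")
        total = sample_gridded_annual_field(field, region, mode="sum")
        assert mean.iloc[0] == pytest.approx(3.0, rel=1e-12)
        assert total.iloc[0] == pytest.approx(6.0, rel=1e-12)

    def test_partial_overlap_uses_area_fraction(self):
        # 0.5-deg box over one quarter of a 1-deg cell: mean is the cell
        # value, sum attributes a quarter of it
        region = square_region("quarter", 10.25, 0.25, 0.5, buffer_km=0.0)
        field = self._field([[8.0]], lons=[10.0], lats=[0.0])
        assert sample_gridded_annual_field(field, region, "mean").iloc[0] == \
            pytest.approx(8.0)
        assert sample_gridded_annual_field(field, region, "sum").iloc[0] == \
            pytest.approx(2.0, rel=1e-9)

    def test_no_overlap_raises(self):
        region = square_region("far", 50.0, 50.0, 0.5)
        field = self._field([[1.0]], lons=[10.0], lats=[0.0])
        with pytest.raises(ValueError, match="overlap"):
            sample_gridded_annual_field(field, region)
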