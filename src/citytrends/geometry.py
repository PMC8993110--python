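"""Region geometries and geographic helpers.

City, ocean-background and rural-reference domains are WGS-84 polygons.
Metric buffering (extending a sampling domain by the instrument footprint,
e.g. 6.5 km for a UV-vis spectrometer pixel) is done in a local azimuthal
equidistant projection about the region centroid, so a buffer distance in
kilometres means kilometres at any latitude.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, box, mapping, shape
from shapely.ops import transform

EARTH_RADIUS_KM = 6371.0

REGION_KINDS = ("city", "ocean_background", "rural_reference")


class EmptyRegionError(ValueError):
    """Raised when an operation receives a degenerate (empty) geometry."""


@dataclass(frozen=True)
class RegionGeometry:
    """A named sampling domain.

    Parameters
    ----------
    region_id:
        Label used in all tabular outputs.
    polygon:
        Closed, non-self-intersecting polygon in geographic (lon, lat)
        coordinates.
    buffer_km:
        Distance by which the sampling domain is dilated beyond the polygon,
        matched to the instrument pixel size (0 disables buffering).
    kind:
        One of ``city``, ``ocean_background``, ``rural_reference``.
    """

    region_id: str
    polygon: Polygon
    buffer_km: float = 0.0
    kind: str = "city"

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"kind must be one of {REGION_KINDS}, got {self.kind!r}")
        if self.buffer_km < 0:
            raise ValueError("buffer_km must be >= 0")
        if self.polygon.is_empty or self.polygon.area == 0:
            raise EmptyRegionError(f"region {self.region_id!r} has an empty geometry")
        if not self.polygon.is_valid:
            raise ValueError(f"region {self.region_id!r} polygon is self-intersecting")

    @property
    def centroid_lonlat(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)

    def sampling_polygon(self) -> Polygon:
        """Polygon dilated by ``buffer_km`` (metric, via local projection)."""
        if self.buffer_km == 0:
            return self.polygon
        lon0, lat0 = self.centroid_lonlat
        fwd, inv = azimuthal_equidistant(lon0, lat0)
        local = transform(fwd, self.polygon)
        return transform(inv, local.buffer(self.buffer_km))

    def contains(self, lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
        """Inclusive point-in-domain test (boundary points count as inside)."""
        poly = self.sampling_polygon()
        pts = shapely.points(np.asarray(lons, float), np.asarray(lats, float))
        return shapely.covers(poly, pts)


def azimuthal_equidistant(lon0: float, lat0: float):
    """Forward/inverse local azimuthal equidistant projection (km).

    Distances from the projection centre are exact on the sphere, which is
    what a metric buffer about a region centroid needs.
    """
    lam0, phi0 = math.radians(lon0), math.radians(lat0)
    sin0, cos0 = math.sin(phi0), math.cos(phi0)

    def fwd(lon, lat):
        lam = np.radians(np.asarray(lon, float))
        phi = np.radians(np.asarray(lat, float))
        cosc = sin0 * np.sin(phi) + cos0 * np.cos(phi) * np.cos(lam - lam0)
        cosc = np.clip(cosc, -1.0, 1.0)
        c = np.arccos(cosc)
        # k -> R as c -> 0
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, EARTH_RADIUS_KM * c / np.sin(c), EARTH_RADIUS_KM)
        x = k * np.cos(phi) * np.sin(lam - lam0)
        y = k * (cos0 * np.sin(phi) - sin0 * np.cos(phi) * np.cos(lam - lam0))
        return x, y

    def inv(x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        rho = np.hypot(x, y)
        c = rho / EARTH_RADIUS_KM
        sinc, cosc = np.sin(c), np.cos(c)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.where(
                rho > 1e-12,
                np.arcsin(cosc * sin0 + y * sinc * cos0 / np.where(rho > 1e-12, rho, 1.0)),
                phi0,
            )
            lam = lam0 + np.arctan2(
                x * sinc, rho * cos0 * cosc - y * sin0 * sinc
            )
        return np.degrees(lam), np.degrees(phi)

    return fwd, inv


def haversine_km(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance between two (lon, lat) points in km."""
    lam1, phi1, lam2, phi2 = map(math.radians, (lon1, lat1, lon2, lat2))
    a = (
        math.sin((phi2 - phi1) / 2) ** 2
        + math.cos(phi1) * math.cos(phi2) * math.sin((lam2 - lam1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def destination_point(lon: float, lat: float, bearing_deg: float, distance_km: float):
    """Point at a given great-circle distance and bearing from (lon, lat)."""
    lam1, phi1 = math.radians(lon), math.radians(lat)
    theta = math.radians(bearing_deg)
    delta = distance_km / EARTH_RADIUS_KM
    phi2 = math.asin(
        math.sin(phi1) * math.cos(delta)
        + math.cos(phi1) * math.sin(delta) * math.cos(theta)
    )
    lam2 = lam1 + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(phi1),
        math.cos(delta) - math.sin(phi1) * math.sin(phi2),
    )
    return math.degrees(lam2), math.degrees(phi2)


def square_region(
    region_id: str,
    center_lon: float,
    center_lat: float,
    size_deg: float,
    buffer_km: float = 0.0,
    kind: str = "city",
) -> RegionGeometry:
    """Axis-aligned square domain of ``size_deg`` × ``size_deg`` degrees."""
    h = size_deg / 2.0
    poly = box(center_lon - h, center_lat - h, center_lon + h, center_lat + h)
    return RegionGeometry(region_id, poly, buffer_km=buffer_km, kind=kind)


def to_geojson(regions, path) -> None:
    """Write regions as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "properties": {
                "region_id": r.region_id,
                "buffer_km": r.buffer_km,
                "kind": r.kind,
            },
            "geometry": mapping(r.polygon),
        }
        for r in regions
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def from_geojson(path) -> list[RegionGeometry]:
    """Read regions from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        doc = json.load(fh)
    regions = []
    for feat in doc["features"]:
        props = feat.get("properties", {})
        regions.append(
            RegionGeometry(
                region_id=props.get("region_id", "region"),
                polygon=shape(feat["geometry"]),
                buffer_km=float(props.get("buffer_km", 0.0)),
                kind=props.get("kind", "city"),
            )
        )
    return regions
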