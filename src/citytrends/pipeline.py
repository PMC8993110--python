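"""End-to-end orchestration: synthesize -> sample -> fit -> partition ->
exposure -> health -> decompose.

Each stage reads only the declared CSV/GeoJSON outputs of earlier stages
and writes tidy CSVs under the run directory, so deleting intermediates and
rerunning reproduces them. Every tabular output starts with a comment
header recording the seed and config hash; reruns with the same config are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import attribution, health, sampling, synthetic, trends
from .geometry import RegionGeometry, from_geojson, square_region, to_geojson

logger = logging.getLogger(__name__)

STAGES = ("synth", "sample", "fit", "partition", "exposure", "health", "decompose")


@dataclass(frozen=True)
class CityConfig:
    """One synthetic city: geometry, truth scenarios, demographics."""

    region_id: str
    center_lon: float
    center_lat: float
    size_deg: float = 0.3
    buffer_km: float = 6.5
    burning_season: str = "northern_africa"
    scenarios: dict[str, synthetic.SyntheticScenario] = field(default_factory=dict)
    demographics: synthetic.DemographicScenario = field(
        default_factory=synthetic.DemographicScenario
    )

    def region(self) -> RegionGeometry:
        return square_region(
            self.region_id, self.center_lon, self.center_lat,
            self.size_deg, buffer_km=self.buffer_km,
        )

    def bb_months(self) -> frozenset[int]:
        return attribution.BURNING_SEASONS[self.burning_season]


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one pipeline run."""

    outdir: Path
    seed: int = 0
    years: tuple[int, int] = (2005, 2018)
    cities: tuple[CityConfig, ...] = ()
    species: tuple[str, ...] = ("NO2", "HCHO", "AOD")
    min_coverage: float = 0.30
    quantile_method: str = "linear"
    crf: health.CRFSpec = field(default_factory=health.CRFSpec)
    record_years: int = health.RECORD_YEARS_DEFAULT

    def validate(self) -> None:
        if not self.cities:
            raise ValueError("config lists no cities")
        ids = [c.region_id for c in self.cities]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region_id in config")
        for c in self.cities:
            if c.burning_season not in attribution.BURNING_SEASONS:
                raise ValueError(
                    f"unknown burning season {c.burning_season!r} "
                    f"for {c.region_id!r}"
                )

    def config_hash(self) -> str:
        blob = repr(
            dataclasses.asdict(
                dataclasses.replace(self, outdir=Path("."))
            )
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, seed: int, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} config={cfg_hash}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _city_seed(config: RunConfig, city_idx: int, tag: int) -> int:
    return int((config.seed * 100003 + city_idx * 1009 + tag) % (2**31 - 1))


def _stage_synth(config: RunConfig, out: Path) -> list[str]:
    written = []
    regions = []
    demo_frames = []
    for i, city in enumerate(config.cities):
        region = city.region()
        regions.append(region)
        for j, (species, scen) in enumerate(sorted(city.scenarios.items())):
            scen = dataclasses.replace(
                scen, seed=_city_seed(config, i, j), years=config.years
            )
            pixels = synthetic.generate_pixels(scen, region)
            path = out / f"pixels_{city.region_id}_{species}.csv"
            _write_csv(pixels, path, scen.seed, config.config_hash())
            written.append(path.name)
            if species == "HCHO":
                # remote ocean background domain over the same latitude range
                ocean = RegionGeometry(
                    f"{city.region_id}_ocean",
                    square_region(
                        "tmp", city.center_lon - 15.0, city.center_lat,
                        city.size_deg,
                    ).polygon,
                    kind="ocean_background",
                )
                bg_scen = dataclasses.replace(
                    scen,
                    rel_trend=0.0,
                    bb_months=frozenset(),
                    bb_excess=0.0,
                    baseline_column=scen.baseline_column * 0.6,
                    seed=_city_seed(config, i, 50 + j),
                )
                bg_pixels = synthetic.generate_pixels(bg_scen, ocean)
                path = out / f"pixels_{city.region_id}_HCHO_background.csv"
                _write_csv(bg_pixels, path, bg_scen.seed, config.config_hash())
                written.append(path.name)
                regions.append(ocean)
        # burned fraction grid centred on the city
        ref = city.scenarios.get("NO2", next(iter(city.scenarios.values())))
        ref = dataclasses.replace(
            ref, seed=_city_seed(config, i, 99), years=config.years
        )
        grid = synthetic.GridSpec(
            lon_min=city.center_lon - 0.5, lat_min=city.center_lat - 0.5,
            nlon=4, nlat=4,
        )
        bf = synthetic.generate_burned_fraction(ref, grid)
        path = out / f"burned_fraction_{city.region_id}.csv"
        synthetic.gridded_field_to_csv(bf, path)
        written.append(path.name)
        demo = synthetic.generate_demographics(
            city.demographics, range(config.years[0], config.years[1] + 1)
        )
        demo.insert(0, "region_id", city.region_id)
        demo_frames.append(demo)
    path = out / "demographics.csv"
    _write_csv(pd.concat(demo_frames), path, config.seed, config.config_hash())
    written.append(path.name)
    to_geojson(regions, out / "regions.geojson")
    written.append("regions.geojson")
    return written


def _stage_sample(config: RunConfig, out: Path) -> list[str]:
    written = []
    regions = {r.region_id: r for r in from_geojson(out / "regions.geojson")}
    span = (f"{config.years[0]}-01", f"{config.years[1]}-12")
    for city in config.cities:
        region = dataclasses.replace(
            regions[city.region_id], buffer_km=city.buffer_km
        )
        for species in sorted(city.scenarios):
            pixels = _read_csv(out / f"pixels_{city.region_id}_{species}.csv")
            series = sampling.sample_region(pixels, region, species, record_span=span)
            path = out / f"series_{city.region_id}_{species}.csv"
            series.to_csv(path)
            written.append(path.name)
            if species == "HCHO":
                bg_pixels = _read_csv(
                    out / f"pixels_{city.region_id}_HCHO_background.csv"
                )
                ocean = regions[f"{city.region_id}_ocean"]
                bg = sampling.background_series(
                    bg_pixels, ocean, paired_city=region, record_span=span
                )
                bg_fit = trends.fit_seasonal_trend(bg, min_coverage=config.min_coverage)
                reactive = sampling.subtract_background(series, bg, bg_fit)
                path = out / f"series_{city.region_id}_HCHO_reactive.csv"
                reactive.to_csv(path)
                written.append(path.name)
    return written


def _fit_species(city: CityConfig) -> list[str]:
    out = sorted(city.scenarios)
    if "HCHO" in out:
        out.append("HCHO_reactive")
    return out


def _stage_fit(config: RunConfig, out: Path) -> list[str]:
    rows = []
    for city in config.cities:
        for species in _fit_species(city):
            series = sampling.MonthlyCitySeries.from_csv(
                out / f"series_{city.region_id}_{species}.csv"
            )
            try:
                fit = trends.fit_seasonal_trend(
                    series, min_coverage=config.min_coverage
                )
                rows.append(
                    {
                        "region_id": city.region_id,
                        "species": species,
                        "baseline": fit.mu0,
                        "beta": fit.beta,
                        "rel_trend_pct": fit.rel_trend,
                        "ci_low": fit.beta_ci[0],
                        "ci_high": fit.beta_ci[1],
                        "amp": fit.amp,
                        "phase_months": fit.phase,
                        "significant": fit.significant,
                        "n_months": fit.n_months_used,
                        "coverage": fit.coverage_fraction,
                        "status": "ok",
                    }
                )
            except trends.InsufficientCoverageError:
                rows.append(
                    {
                        "region_id": city.region_id,
                        "species": species,
                        "status": "insufficient coverage",
                        "n_months": series.n_retained,
                        "coverage": series.n_retained
                        / max(series.months_in_record, 1),
                    }
                )
    df = pd.DataFrame(rows)
    _write_csv(df, out / "trend_fits.csv", config.seed, config.config_hash())
    return ["trend_fits.csv"]


def _stage_partition(config: RunConfig, out: Path) -> list[str]:
    rows = []
    regions = {r.region_id: r for r in from_geojson(out / "regions.geojson")}
    for city in config.cities:
        region = dataclasses.replace(
            regions[city.region_id], buffer_km=city.buffer_km
        )
        bf = synthetic.gridded_field_from_csv(
            out / f"burned_fraction_{city.region_id}.csv"
        )
        bf_annual = sampling.sample_gridded_annual_field(bf, region, mode="mean")
        bf_fit = trends.theil_sen(bf_annual.index.to_numpy(float), bf_annual.to_numpy())
        for species in _fit_species(city):
            if species == "AOD":
                continue
            series = sampling.MonthlyCitySeries.from_csv(
                out / f"series_{city.region_id}_{species}.csv"
            )
            part = attribution.partition(
                series, city.bb_months(), quantile_method=config.quantile_method
            )
            try:
                bb_fit, anth_fit = attribution.partition_trends(part)
            except ValueError as exc:
                rows.append(
                    {"region_id": city.region_id, "species": species,
                     "status": f"refused: {exc}"}
                )
                continue
            anth0 = part.annual_anth_series().iloc[0]
            rows.append(
                {
                    "region_id": city.region_id,
                    "species": species,
                    "bb_slope": bb_fit.slope,
                    "bb_significant": bb_fit.significant,
                    "anth_slope": anth_fit.slope,
                    "anth_significant": anth_fit.significant,
                    "anth_rel_trend_pct": trends.relative_trend(anth_fit, anth0)
                    if anth0 > 0 else np.nan,
                    "burned_fraction_slope": bf_fit.slope,
                    "consistency": attribution.consistency_with_burned_fraction(
                        bb_fit, bf_fit
                    ),
                    "eligible": part.eligible(),
                    "status": "ok",
                }
            )
    _write_csv(
        pd.DataFrame(rows), out / "partitions.csv", config.seed, config.config_hash()
    )
    return ["partitions.csv"]


def _stage_exposure(config: RunConfig, out: Path) -> list[str]:
    demo = _read_csv(out / "demographics.csv")
    rows = []
    y0, y1 = config.years
    for city in config.cities:
        d = demo[demo["region_id"] == city.region_id].set_index("year")
        for species in ("AOD", "NO2"):
            if species not in city.scenarios:
                continue
            series = sampling.MonthlyCitySeries.from_csv(
                out / f"series_{city.region_id}_{species}.csv"
            )
            try:
                fit = trends.fit_seasonal_trend(series, min_coverage=config.min_coverage)
            except trends.InsufficientCoverageError:
                rows.append(
                    {"region_id": city.region_id, "species": species,
                     "status": "insufficient coverage"}
                )
                continue
            e0 = health.population_exposure(d.loc[y0, "population"], fit, y0)
            e1 = health.population_exposure(d.loc[y1, "population"], fit, y1)
            rows.append(
                {
                    "region_id": city.region_id,
                    "species": species,
                    "E_start": e0,
                    "E_end": e1,
                    "rel_exposure_trend_pct": health.exposure_trend(
                        e0, e1, y1 - y0
                    ),
                    "status": "ok",
                }
            )
    _write_csv(
        pd.DataFrame(rows), out / "exposure.csv", config.seed, config.config_hash()
    )
    return ["exposure.csv"]


def _stage_health(config: RunConfig, out: Path) -> list[str]:
    demo = _read_csv(out / "demographics.csv")
    y0, y1 = config.years
    rows = []
    for city in config.cities:
        if "AOD" not in city.scenarios:
            continue
        d = demo[demo["region_id"] == city.region_id].set_index("year")
        series = sampling.MonthlyCitySeries.from_csv(
            out / f"series_{city.region_id}_AOD.csv"
        )
        try:
            fit = trends.fit_seasonal_trend(series, min_coverage=config.min_coverage)
        except trends.InsufficientCoverageError:
            # mirrors the convention of summing only cities with a
            # discernible AOD trend
            continue
        dg = city.demographics
        pm = health.pm25_timeseries(
            dg.anchor_pm25, fit, [y0, y1], anchor_year=dg.anchor_year
        )
        for year in (y0, y1):
            af = health.attributable_fraction(pm[year], config.crf)
            est = health.premature_deaths(
                d.loc[year, "population"],
                d.loc[year, "frac_over14"],
                d.loc[year, "y0"],
                af,
                region_id=city.region_id,
                year=year,
                pm25=pm[year],
            )
            rows.append(
                {
                    "region_id": city.region_id,
                    "year": year,
                    "pm25": est.pm25,
                    "attributable_fraction": est.attributable_fraction,
                    "deaths": est.deaths,
                    "deaths_low": est.deaths_low,
                    "deaths_high": est.deaths_high,
                }
            )
    _write_csv(
        pd.DataFrame(rows), out / "mortality.csv", config.seed, config.config_hash()
    )
    return ["mortality.csv"]


def _stage_decompose(config: RunConfig, out: Path) -> list[str]:
    mort = _read_csv(out / "mortality.csv")
    demo = _read_csv(out / "demographics.csv")
    y0, y1 = config.years
    rows = []
    for city in config.cities:
        m = mort[mort["region_id"] == city.region_id].set_index("year")
        if y0 not in m.index or y1 not in m.index:
            continue
        d = demo[demo["region_id"] == city.region_id].set_index("year")
        def inputs(year):
            return {
                "pm25": m.loc[year, "pm25"],
                "population": d.loc[year, "population"],
                "frac_over14": d.loc[year, "frac_over14"],
                "y0": d.loc[year, "y0"],
            }
        dec = health.decompose_factors(
            inputs(y0), inputs(y1), config.crf, reference=(y0, y1)
        )
        change = health.mortality_change(
            m.loc[y0, "deaths"], m.loc[y1, "deaths"], config.record_years
        )
        rows.append(
            {
                "region_id": city.region_id,
                "deaths_change": change["absolute"],
                "deaths_change_pct": change["relative_pct"],
                "deaths_change_per_year": change["per_year"],
                "log_ratio_pm25": dec.log_ratio["pm25"],
                "log_ratio_population": dec.log_ratio["population"],
                "log_ratio_baseline_mortality": dec.log_ratio["baseline_mortality"],
                "log_ratio_total": dec.total,
            }
        )
    _write_csv(
        pd.DataFrame(rows), out / "decomposition.csv", config.seed,
        config.config_hash(),
    )
    return ["decomposition.csv"]


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "sample": _stage_sample,
    "fit": _stage_fit,
    "partition": _stage_partition,
    "exposure": _stage_exposure,
    "health": _stage_health,
    "decompose": _stage_decompose,
}


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; return (and write) the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": [],
        "status": "complete",
    }
    for stage in STAGES:
        try:
            outputs = _STAGE_FUNCS[stage](config, out)
        except Exception as exc:  # record partial completion, re-raise
            manifest["status"] = f"failed at {stage}: {exc}"
            manifest["stages"].append({"name": stage, "status": "failed"})
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=1)
            raise
        manifest["stages"].append(
            {"name": stage, "status": "ok", "outputs": outputs}
        )
        logger.info("stage %s: %d outputs", stage, len(outputs))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def summarize(outdir) -> dict[str, pd.DataFrame]:
    """Per-city summary tables from a completed run."""
    out = Path(outdir)
    tables = {
        "trends": _read_csv(out / "trend_fits.csv"),
        "partitions": _read_csv(out / "partitions.csv"),
        "exposure": _read_csv(out / "exposure.csv"),
        "mortality": _read_csv(out / "mortality.csv"),
        "decomposition": _read_csv(out / "decomposition.csv"),
    }
    mort = tables["mortality"]
    if not mort.empty:
        wide = mort.pivot(index="region_id", columns="year")
        years = sorted(mort["year"].unique())
        summary = pd.DataFrame(
            {
                f"pm25_{years[0]}": wide[("pm25", years[0])],
                f"pm25_{years[-1]}": wide[("pm25", years[-1])],
                f"deaths_{years[0]}": wide[("deaths", years[0])],
                f"deaths_{years[-1]}": wide[("deaths", years[-1])],
                "change": wide[("deaths", years[-1])] - wide[("deaths", years[0])],
            }
        ).reset_index()
        tables["mortality_summary"] = summary
    return tables


def demo_config(outdir, seed: int = 0) -> RunConfig:
    """Bundled three-city synthetic scenario (runs end-to-end in seconds)."""
    mk = synthetic.SyntheticScenario
    cities = (
        CityConfig(
            region_id="alpha",
            center_lon=3.4, center_lat=6.5,            # coastal West Africa
            burning_season="northern_africa",
            scenarios={
                "NO2": mk(baseline_column=2.0, rel_trend=0.04,
                          seasonal_amplitude=0.15, bb_months=frozenset({12, 1, 2, 3}),
                          bb_excess=0.3, bb_trend=-0.02, noise_sd=0.05,
                          gap_prob=0.1),
                "HCHO": mk(baseline_column=8.0, rel_trend=0.015,
                           seasonal_amplitude=0.1, bb_months=frozenset({12, 1, 2, 3}),
                           bb_excess=0.25, bb_trend=0.0, noise_sd=0.05,
                           gap_prob=0.1),
                "AOD": mk(baseline_column=0.5, rel_trend=0.02,
                          seasonal_amplitude=0.2, noise_sd=0.05, gap_prob=0.1),
            },
            demographics=synthetic.DemographicScenario(
                pop_start=8e6, pop_growth=0.035, frac_over14=0.6,
                # baseline mortality declines ~2%/a, partly offsetting growth
                y0_by_year={y: 0.010 * 0.98 ** (y - 2005) for y in range(2005, 2019)},
                y0_default=0.009, anchor_pm25=40.0,
            ),
        ),
        CityConfig(
            region_id="beta",
            center_lon=88.4, center_lat=22.6,          # South Asia
            burning_season="south_asia",
            scenarios={
                "NO2": mk(baseline_column=5.0, rel_trend=0.06,
                          seasonal_amplitude=0.2, bb_months=frozenset({1, 2, 3, 4}),
                          bb_excess=0.2, bb_trend=0.01, noise_sd=0.05,
                          gap_prob=0.15),
                "HCHO": mk(baseline_column=10.0, rel_trend=0.03,
                           seasonal_amplitude=0.15, bb_months=frozenset({1, 2, 3, 4}),
                           bb_excess=0.2, bb_trend=0.01, noise_sd=0.05,
                           gap_prob=0.15),
                "AOD": mk(baseline_column=0.7, rel_trend=0.05,
                          seasonal_amplitude=0.25, noise_sd=0.05, gap_prob=0.1),
            },
            demographics=synthetic.DemographicScenario(
                pop_start=14e6, pop_growth=0.02, frac_over14=0.75,
                y0_default=0.007, anchor_pm25=70.0,
            ),
        ),
        CityConfig(
            region_id="gamma",
            center_lon=106.8, center_lat=-6.2,         # Southeast Asia, south
            burning_season="southeast_asia_south",
            scenarios={
                "NO2": mk(baseline_column=6.0, rel_trend=-0.02,
                          seasonal_amplitude=0.15, bb_months=frozenset({8, 9, 10}),
                          bb_excess=0.15, bb_trend=0.0, noise_sd=0.05,
                          gap_prob=0.1),
                "HCHO": mk(baseline_column=9.0, rel_trend=-0.017,
                           seasonal_amplitude=0.1, bb_months=frozenset({8, 9, 10}),
                           bb_excess=0.15, bb_trend=0.0, noise_sd=0.05,
                           gap_prob=0.1),
                "AOD": mk(baseline_column=0.6, rel_trend=0.005,
                          seasonal_amplitude=0.15, noise_sd=0.05, gap_prob=0.1),
            },
            demographics=synthetic.DemographicScenario(
                pop_start=10e6, pop_growth=0.013, frac_over14=0.72,
                # ageing population: baseline mortality creeps up
                y0_by_year={y: 0.0065 * 1.005 ** (y - 2005) for y in range(2005, 2019)},
                y0_default=0.0065, anchor_pm25=35.0,
            ),
        ),
    )
    return RunConfig(outdir=Path(outdir), seed=seed, cities=cities)
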