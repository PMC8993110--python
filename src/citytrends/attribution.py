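"""Biomass-burning vs anthropogenic source partitioning.

Each calendar year's retained monthly means are split at that year's 75th
percentile. Months at or below the percentile are the non-biomass-burning
(anthropogenic activity) data; their annual mean is the year's anthropogenic
level. Burning-season months strictly above the percentile, minus that
anthropogenic level, form the biomass-burning excess. Annualized versions
of both components are trended with the Theil-Sen estimator, and the sign
of the burning trend is checked against the trend in satellite burned
fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sampling import MonthlyCitySeries
from .trends import TheilSenFit, theil_sen

# burning-season calendars by region (month-of-year indices); editable config
BURNING_SEASONS: dict[str, frozenset[int]] = {
    "northern_africa": frozenset({12, 1, 2, 3}),
    "southern_africa": frozenset({7, 8, 9, 10, 11}),
    "south_asia": frozenset({1, 2, 3, 4}),
    "southeast_asia_north": frozenset({1, 2, 3, 4}),
    "southeast_asia_south": frozenset({8, 9, 10}),
}


@dataclass
class SourcePartition:
    """Per-year 75th-percentile split of a monthly series."""

    region_id: str
    species: str
    p75_by_year: dict[int, float]
    anth_annual_mean: dict[int, float]
    bb_excess: pd.DataFrame          # columns: year, month, value, excess
    bb_month_set: frozenset[int]
    overlap_check: dict[int, bool] = field(default_factory=dict)

    def annual_bb_series(self) -> pd.Series:
        """Per-year mean of monthly biomass-burning excess."""
        if self.bb_excess.empty:
            return pd.Series(dtype=float, name="bb")
        return self.bb_excess.groupby("year")["excess"].mean().rename("bb")

    def annual_anth_series(self) -> pd.Series:
        return pd.Series(self.anth_annual_mean, name="anth").sort_index()

    def eligible(self) -> bool:
        """Burning-influenced city test: overlap holds in >= half the years."""
        if not self.overlap_check:
            return False
        ok = sum(self.overlap_check.values())
        return ok >= len(self.overlap_check) / 2.0


def partition(
    series: MonthlyCitySeries,
    bb_month_set,
    min_months_per_year: int = 8,
    quantile_method: str = "linear",
) -> SourcePartition:
    """Split a monthly series into burning and anthropogenic components.

    Years with fewer than ``min_months_per_year`` retained months are not
    partitioned (a 75th percentile over very few months is meaningless).
    The percentile uses linear interpolation between order statistics by
    default; months exactly equal to it classify as anthropogenic.
    ``overlap_check[year]`` is True when every above-percentile month of the
    year falls in the prescribed burning season.
    """
    bb_month_set = frozenset(int(m) for m in bb_month_set)
    if not bb_month_set <= set(range(1, 13)):
        raise ValueError("bb_month_set must be a subset of {1..12}")
    ret = series.data[series.data["retained"]]
    p75: dict[int, float] = {}
    anth: dict[int, float] = {}
    overlap: dict[int, bool] = {}
    bb_rows = []
    for year, grp in ret.groupby("year"):
        vals = grp["mean"].to_numpy(float)
        if len(vals) < min_months_per_year:
            continue
        q = float(np.quantile(vals, 0.75, method=quantile_method))
        above = grp[grp["mean"] > q]
        below = grp[grp["mean"] <= q]
        if above.empty:
            warnings.warn(
                f"{series.region_id!r} {year}: all retained months tied; "
                "burning set empty"
            )
        p75[int(year)] = q
        anth_mean = float(below["mean"].mean())
        anth[int(year)] = anth_mean
        overlap[int(year)] = bool(
            above["month"].isin(list(bb_month_set)).all()
        )
        for rec in above.itertuples(index=False):
            if int(rec.month) in bb_month_set:
                bb_rows.append(
                    (int(year), int(rec.month), float(rec.mean),
                     float(rec.mean) - anth_mean)
                )
    bb = pd.DataFrame(bb_rows, columns=["year", "month", "value", "excess"])
    return SourcePartition(
        region_id=series.region_id,
        species=series.species,
        p75_by_year=p75,
        anth_annual_mean=anth,
        bb_excess=bb,
        bb_month_set=bb_month_set,
        overlap_check=overlap,
    )


def partition_trends(
    part: SourcePartition, min_years: int = 3
) -> tuple[TheilSenFit, TheilSenFit]:
    """Theil-Sen trends of the annualized burning and anthropogenic series."""
    bb = part.annual_bb_series()
    anth = part.annual_anth_series()
    if bb.empty and len(anth) >= min_years:
        # no month ever exceeded its year's percentile (e.g. a flat series):
        # the burning component is identically zero, and so is its trend
        bb = pd.Series(0.0, index=anth.index, name="bb")
    if len(bb) < min_years or len(anth) < min_years:
        raise ValueError(
            f"need >= {min_years} years on each side; have "
            f"{len(bb)} burning and {len(anth)} anthropogenic years"
        )
    bb_fit = theil_sen(bb.index.to_numpy(float), bb.to_numpy())
    anth_fit = theil_sen(anth.index.to_numpy(float), anth.to_numpy())
    return bb_fit, anth_fit


def consistency_with_burned_fraction(
    bb_fit: TheilSenFit, bf_fit: TheilSenFit
) -> str:
    """Direction agreement between burning excess and burned-fraction trends.

    Returns ``consistent`` when both 95% CIs exclude zero and the slopes
    share a sign, ``opposite`` when both exclude zero with opposing signs,
    and ``indeterminate`` when either CI spans zero.
    """
    if not (bb_fit.significant and bf_fit.significant):
        return "indeterminate"
    return "consistent" if bb_fit.slope * bf_fit.slope > 0 else "opposite"
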