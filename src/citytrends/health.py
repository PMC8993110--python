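"""Population exposure, PM2.5-attributable mortality and factor decomposition.

Exposure follows E_pop = N * C: total city population times the annual mean
of the fitted pollutant proxy (column NO2 for surface NO2, AOD for surface
PM2.5). Absolute PM2.5 comes from anchoring the AOD fit to a modelled
concentration at the record midpoint and scaling the whole record by the
fitted AOD ratio.

Premature mortality attributable to PM2.5 uses the attributable fraction
AF = 1 - 1/RR(c) with a configurable concentration-response function (CRF):
a piecewise log-linear relative risk RR(c) = exp(beta(c) * (c - c0)) above a
counterfactual concentration c0, with central/low/high beta curves driving
the 95% CI. Deaths = population * fraction over 14 * baseline mortality
rate * AF. The change between two years is decomposed into PM2.5,
population and baseline-mortality contributions by log-ratios: each factor
held at start-year values with the others at end-year values, relative to
the all-end-year estimate. For this multiplicative model the factor
log-ratios sum exactly to ln(M_start / M_end).

The default CRF coefficients shipped here are illustrative (a ~8% risk
increase per 10 ug m-3 below 50 ug m-3, attenuating above, with a wide
uncertainty band at high concentrations); absolute death counts depend
entirely on the CRF supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trends import SeasonalTrendFit

RECORD_YEARS_DEFAULT = 14  # 2005-2018 inclusive


@dataclass(frozen=True)
class CRFSpec:
    """Piecewise log-linear concentration-response function.

    ``conc_grid`` and the three beta rows define beta(c) by linear
    interpolation (constant extrapolation beyond the grid); RR(c) = 1 at and
    below the counterfactual ``counterfactual_c0``.
    """

    counterfactual_c0: float = 4.5           # ug m-3
    conc_grid: tuple[float, ...] = (0.0, 50.0, 100.0, 150.0)
    beta_central: tuple[float, ...] = (0.0077, 0.0077, 0.0060, 0.0050)
    beta_low: tuple[float, ...] = (0.0058, 0.0058, 0.0040, 0.0030)
    beta_high: tuple[float, ...] = (0.0092, 0.0092, 0.0110, 0.0105)
    age_floor: int = 14

    def __post_init__(self) -> None:
        n = len(self.conc_grid)
        if any(len(b) != n for b in (self.beta_central, self.beta_low, self.beta_high)):
            raise ValueError("beta rows must match conc_grid length")
        # RR must be non-decreasing in concentration for each variant
        scan = np.linspace(0.0, max(self.conc_grid) * 1.5, 400)
        for variant in ("low", "central", "high"):
            rr = self.relative_risk(scan, variant)
            if np.any(np.diff(rr) < -1e-12):
                raise ValueError(f"RR not non-decreasing for {variant} betas")

    def _beta(self, c, variant: str) -> np.ndarray:
        row = {
            "central": self.beta_central,
            "low": self.beta_low,
            "high": self.beta_high,
        }[variant]
        return np.interp(np.asarray(c, float), self.conc_grid, row)

    def relative_risk(self, c, variant: str = "central") -> np.ndarray:
        c = np.asarray(c, float)
        excess = np.clip(c - self.counterfactual_c0, 0.0, None)
        return np.exp(self._beta(c, variant) * excess)


@dataclass
class MortalityEstimate:
    """Attributable premature deaths for one city-year."""

    region_id: str
    year: int
    pm25: float
    attributable_fraction: float                # central
    deaths: float                               # central
    deaths_low: float
    deaths_high: float
    total_deaths_over14: float

    def __post_init__(self) -> None:
        if not self.deaths_low <= self.deaths <= self.deaths_high:
            raise ValueError("mortality CI must bracket the central estimate")


@dataclass
class DecompositionResult:
    """Log-ratio contributions of PM2.5, population and baseline mortality."""

    log_ratio: dict[str, float]
    reference: tuple[int, int]

    @property
    def total(self) -> float:
        return sum(self.log_ratio.values())


def population_exposure(N: float, fit: SeasonalTrendFit, year: int) -> float:
    """E_pop = N * annual mean of the fitted pollutant proxy in ``year``."""
    if N < 0:
        raise ValueError("population must be >= 0")
    return N * fit.annual_mean(year)


def exposure_trend(E_start: float, E_end: float, n_years: int) -> float:
    """Relative exposure trend in percent of the start value per year."""
    if E_start <= 0:
        raise ValueError("E_start must be > 0")
    return 100.0 * ((E_end - E_start) / E_start) / n_years


def compose_trends(pop_pct: float, conc_pct: float) -> dict[str, float]:
    """First-order additive composition of component trends (percent/year).

    The exposure trend is population trend + concentration trend to first
    order; the multiplicative cross-term is reported separately.
    """
    return {
        "additive": pop_pct + conc_pct,
        "cross_term": pop_pct * conc_pct / 100.0,
    }


def pm25_timeseries(
    anchor_pm25: float,
    aod_fit: SeasonalTrendFit,
    years,
    anchor_year: int = 2012,
) -> pd.Series:
    """Absolute PM2.5 per year from an anchored AOD fit.

    PM2.5(y) = anchor * C_fit(y) / C_fit(anchor_year), with C_fit the annual
    mean of the fitted AOD curve. Scaling the anchor scales every year by
    the same factor.
    """
    c_anchor = aod_fit.annual_mean(anchor_year)
    if c_anchor <= 0:
        raise ValueError(
            f"fitted AOD annual mean at anchor year {anchor_year} is "
            f"non-positive ({c_anchor:.3g})"
        )
    vals = {int(y): anchor_pm25 * aod_fit.annual_mean(int(y)) / c_anchor for y in years}
    return pd.Series(vals, name="pm25").sort_index()


def attributable_fraction(c: float, crf: CRFSpec) -> dict[str, float]:
    """AF = 1 - 1/RR(c) with central/low/high CRF variants."""
    if c < 0:
        raise ValueError("concentration must be >= 0")
    return {
        v: float(1.0 - 1.0 / crf.relative_risk(c, v))
        for v in ("central", "low", "high")
    }


def premature_deaths(
    pop,
    frac_over14,
    y0,
    af: dict[str, float],
    region_id: str = "city",
    year: int = 0,
    pm25: float = float("nan"),
) -> MortalityEstimate:
    """Attributable deaths: pop * frac_over14 * y0 * AF, summed over strata.

    Scalar inputs describe a single >=14 stratum; array-likes of equal
    length describe multiple strata and are summed.
    """
    pop = np.atleast_1d(np.asarray(pop, float))
    frac = np.atleast_1d(np.asarray(frac_over14, float))
    y0 = np.atleast_1d(np.asarray(y0, float))
    if np.any(pop < 0) or np.any(y0 < 0) or np.any((frac < 0) | (frac > 1)):
        raise ValueError("inputs must be >= 0 with frac_over14 <= 1")
    base = float((pop * frac * y0).sum())
    lo, mid, hi = sorted((af["low"], af["central"], af["high"]))
    return MortalityEstimate(
        region_id=region_id,
        year=year,
        pm25=pm25,
        attributable_fraction=af["central"],
        deaths=base * af["central"],
        deaths_low=base * lo,
        deaths_high=base * hi,
        total_deaths_over14=base,
    )


def mortality_change(start, end, record_years: int = RECORD_YEARS_DEFAULT):
    """Absolute, relative and per-year change in attributable deaths.

    Accepts MortalityEstimate objects or plain death counts. The per-year
    average divides by the length of the observing period in years.
    """
    s = start.deaths if isinstance(start, MortalityEstimate) else float(start)
    e = end.deaths if isinstance(end, MortalityEstimate) else float(end)
    if s <= 0:
        raise ValueError("start deaths must be > 0")
    return {
        "absolute": e - s,
        "relative_pct": 100.0 * (e - s) / s,
        "per_year": (e - s) / record_years,
    }


def _deaths_single(pm25, pop, frac, y0, crf: CRFSpec) -> float:
    af = attributable_fraction(pm25, crf)["central"]
    return pop * frac * y0 * af


def decompose_factors(
    inputs_start: dict,
    inputs_end: dict,
    crf: CRFSpec,
    reference: tuple[int, int] = (2005, 2018),
) -> DecompositionResult:
    """Log-ratio decomposition of the mortality change into its drivers.

    Each input dict carries ``pm25``, ``population``, ``frac_over14`` and
    ``y0``. For factor k the log-ratio is ln(M with k at start-year values,
    all else at end-year values / M with everything at end-year values).
    Population and its over-14 fraction travel together as the population
    factor. Because deaths are multiplicative in the three factors, the
    log-ratios sum exactly to ln(M_start / M_end).
    """
    def m(pm, pop, frac, y0):
        return _deaths_single(pm, pop, frac, y0, crf)

    s, e = inputs_start, inputs_end
    m_end = m(e["pm25"], e["population"], e["frac_over14"], e["y0"])
    m_start = m(s["pm25"], s["population"], s["frac_over14"], s["y0"])
    if m_end <= 0 or m_start <= 0:
        raise ValueError("deaths must be > 0 in both years to decompose")
    ratios = {
        "pm25": m(s["pm25"], e["population"], e["frac_over14"], e["y0"]) / m_end,
        "population": m(e["pm25"], s["population"], s["frac_over14"], e["y0"]) / m_end,
        "baseline_mortality": m(e["pm25"], e["population"], e["frac_over14"], s["y0"]) / m_end,
    }
    return DecompositionResult(
        log_ratio={k: math.log(v) for k, v in ratios.items()},
        reference=reference,
    )
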