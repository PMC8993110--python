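"""Seasonal-trend fitting, Theil-Sen slopes and ozone-regime diagnostics.

The seasonal-trend model for a monthly series is

    f(t) = mu0 + beta * t + amp * sin(2*pi*t + phase)

with t in years from the record start: a record-start baseline mu0, an
absolute linear trend beta (units per year) and one annual harmonic with
free amplitude and phase (an optional semi-annual harmonic can be added).
Writing amp*sin(2*pi*t + phase) = a*sin(2*pi*t) + b*cos(2*pi*t) makes the
model linear in its parameters, so it is fit by ordinary least squares and
the 95% CI on beta comes from the exact parameter covariance (a
block-by-year bootstrap is available as an alternative). A trend is called
significant when the 95% CI on beta excludes zero.

Relative trends are reported as percent of the record-start baseline per
year: 100 * beta / mu0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sampling import MonthlyCitySeries

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


class InsufficientCoverageError(ValueError):
    """Series temporal coverage is below the fitting gate (>30% of record)."""


@dataclass
class SeasonalTrendFit:
    """Fitted seasonal+linear model for one monthly series."""

    region_id: str
    species: str
    mu0: float                      # fitted baseline at record start
    beta: float                     # absolute trend, units per year
    amp: float                      # annual seasonal amplitude
    phase: float                    # months, in [0, 12)
    beta_ci: tuple[float, float]    # 95% CI
    rel_trend: float                # percent per year, 100*beta/mu0
    significant: bool
    n_months_used: int
    coverage_fraction: float
    record_start: pd.Period
    record_end: pd.Period
    coeffs: np.ndarray              # [mu0, beta, a1, b1(, a2, b2)]
    ci_method: str = "covariance"

    def predict_t(self, t) -> np.ndarray:
        """Fitted curve at times t (years from record start)."""
        t = np.asarray(t, float)
        X = _design_matrix(t, harmonics=(len(self.coeffs) - 2) // 2)
        return X @ self.coeffs

    def predict_months(self, periods: pd.PeriodIndex) -> np.ndarray:
        t = np.array([(p - self.record_start).n / 12.0 for p in periods])
        return self.predict_t(t)

    def annual_mean(self, year: int) -> float:
        """Annual mean of the fitted curve over the 12 months of ``year``.

        Raises for years outside the record.
        """
        if not self.record_start.year <= year <= self.record_end.year:
            raise ValueError(
                f"year {year} outside record "
                f"{self.record_start.year}-{self.record_end.year}"
            )
        first = (pd.Period(f"{year}-01", "M") - self.record_start).n
        t = (first + np.arange(12)) / 12.0
        return float(self.predict_t(t).mean())


@dataclass
class TheilSenFit:
    """Robust linear trend: median of all pairwise slopes."""

    slope: float                    # units per year
    intercept: float
    slope_ci: tuple[float, float]   # 95% CI (rank-based)
    n_points: int

    @property
    def significant(self) -> bool:
        lo, hi = self.slope_ci
        return not (lo <= 0.0 <= hi)


@dataclass
class RegimeDiagnostic:
    """Ozone-production regime from the HCHO/NO2 column ratio."""

    region_id: str
    annual_ratio: pd.Series         # indexed by year
    threshold: float
    crossing_year: int | None
    degenerate: bool = False
    trend: TheilSenFit | None = None


def _design_matrix(t: np.ndarray, harmonics: int = 1) -> np.ndarray:
    cols = [np.ones_like(t), t]
    for k in range(1, harmonics + 1):
        cols.append(np.sin(TWO_PI * k * t))
        cols.append(np.cos(TWO_PI * k * t))
    return np.column_stack(cols)


def fit_seasonal_trend(
    series: MonthlyCitySeries,
    min_coverage: float = 0.30,
    harmonics: int = 1,
    ci_method: str = "covariance",
    n_boot: int = 500,
    seed: int = 0,
) -> SeasonalTrendFit:
    """Fit the seasonal+linear model to the retained months of a series.

    Only months flagged ``retained`` enter the fit, and the fit refuses
    series whose temporal coverage (retained months / months in record) is
    at or below ``min_coverage`` — for a 168-month record the default gate
    requires more than 50 months.

    Parameters
    ----------
    ci_method:
        ``"covariance"`` (default) takes the 95% CI on beta from the OLS
        parameter covariance with a t critical value; ``"bootstrap"``
        block-resamples calendar years and takes percentile bounds.
    """
    ret = series.retained()
    n_used = len(ret)
    months_total = series.months_in_record
    coverage = n_used / months_total if months_total else 0.0
    if coverage <= min_coverage:
        raise InsufficientCoverageError(
            f"insufficient coverage for {series.region_id!r} {series.species}: "
            f"{n_used}/{months_total} months ({coverage:.0%}) <= "
            f"{min_coverage:.0%} gate"
        )
    t = ret["t"].to_numpy()
    y = ret["mean"].to_numpy(float)
    X = _design_matrix(t, harmonics)
    p = X.shape[1]
    if n_used <= p:
        raise InsufficientCoverageError(
            f"only {n_used} retained months for {p} parameters"
        )
    coeffs, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coeffs
    dof = n_used - p
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se_beta = float(np.sqrt(cov[1, 1]))
    mu0, beta = float(coeffs[0]), float(coeffs[1])
    if ci_method == "covariance":
        tcrit = stats.t.ppf(0.975, dof)
        ci = (beta - tcrit * se_beta, beta + tcrit * se_beta)
    elif ci_method == "bootstrap":
        ci = _bootstrap_beta_ci(ret, harmonics, n_boot, seed)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    # numerical floor so an exactly-interpolated series (zero residuals,
    # beta ~ machine epsilon) is not declared significant
    tol = 1e-10 * max(1.0, float(np.max(np.abs(y))))
    significant = bool(ci[0] > tol or ci[1] < -tol)
    a1, b1 = float(coeffs[2]), float(coeffs[3])
    amp = float(np.hypot(a1, b1))
    phase = float((np.arctan2(b1, a1) % TWO_PI) * 12.0 / TWO_PI)
    periods = series.periods()
    return SeasonalTrendFit(
        region_id=series.region_id,
        species=series.species,
        mu0=mu0,
        beta=beta,
        amp=amp,
        phase=phase,
        beta_ci=(float(ci[0]), float(ci[1])),
        rel_trend=100.0 * beta / mu0 if mu0 != 0 else float("nan"),
        significant=significant,
        n_months_used=n_used,
        coverage_fraction=coverage,
        record_start=periods[0],
        record_end=periods[-1],
        coeffs=coeffs,
        ci_method=ci_method,
    )


def _bootstrap_beta_ci(ret: pd.DataFrame, harmonics: int, n_boot: int, seed: int):
    """Percentile CI on beta from resampling whole calendar years."""
    rng = np.random.default_rng(seed)
    years = ret["year"].unique()
    by_year = {y: ret[ret["year"] == y] for y in years}
    betas = np.empty(n_boot)
    for i in range(n_boot):
        pick = rng.choice(years, size=len(years), replace=True)
        boot = pd.concat([by_year[y] for y in pick])
        X = _design_matrix(boot["t"].to_numpy(), harmonics)
        coeffs, _, _, _ = np.linalg.lstsq(
            X, boot["mean"].to_numpy(float), rcond=None
        )
        betas[i] = coeffs[1]
    return tuple(np.percentile(betas, [2.5, 97.5]))


def theil_sen(years, values) -> TheilSenFit:
    """Theil-Sen median trend on annual (year, value) pairs.

    The slope is the median of all C(n,2) pairwise slopes (midpoint of the
    two central order statistics for even counts); the 95% CI is the
    rank-based interval on the ordered pairwise slopes.
    """
    years = np.asarray(years, float)
    values = np.asarray(values, float)
    if len(years) != len(values):
        raise ValueError("years and values must have equal length")
    if len(years) < 3:
        raise ValueError("Theil-Sen needs at least 3 points")
    if len(np.unique(years)) != len(years):
        raise ValueError("duplicate years in Theil-Sen input")
    slope, intercept, lo, hi = stats.theilslopes(values, years, alpha=0.95)
    return TheilSenFit(
        slope=float(slope),
        intercept=float(intercept),
        slope_ci=(float(lo), float(hi)),
        n_points=len(years),
    )


def relative_trend(fit, baseline: float) -> float:
    """Percent-per-year trend relative to a record-start baseline."""
    if baseline <= 0:
        raise ValueError(f"baseline must be > 0, got {baseline}")
    absolute = fit.beta if isinstance(fit, SeasonalTrendFit) else fit.slope
    return 100.0 * absolute / baseline


def ozone_regime(
    hcho_total: MonthlyCitySeries,
    no2: MonthlyCitySeries,
    threshold: float = 2.0,
    horizon_years: int = 20,
) -> RegimeDiagnostic:
    """HCHO/NO2 regime diagnostic with threshold-crossing projection.

    The annual ratio is the ratio of annual means over months retained in
    both series. Ratios above ``threshold`` indicate NOx-sensitive ozone
    production; the crossing year — when the Theil-Sen line through the
    annual ratios first reaches the threshold — is reported only if it
    falls within ``horizon_years`` beyond the record end.
    """
    left = hcho_total.data[hcho_total.data["retained"]][["year", "month", "mean"]]
    right = no2.data[no2.data["retained"]][["year", "month", "mean"]]
    both = left.merge(right, on=["year", "month"], suffixes=("_hcho", "_no2"))
    if both.empty:
        raise ValueError("no overlapping retained months between HCHO and NO2")
    annual = both.groupby("year").agg(
        hcho=("mean_hcho", "mean"), no2=("mean_no2", "mean")
    )
    bad = annual["no2"] <= 0
    if bad.any():
        warnings.warn(
            f"omitting years with non-positive NO2 annual mean: "
            f"{list(annual.index[bad])}"
        )
        annual = annual[~bad]
    ratio = annual["hcho"] / annual["no2"]
    ratio.name = "hcho_no2_ratio"
    years = ratio.index.to_numpy(float)
    crossing: int | None = None
    degenerate = False
    ts_fit: TheilSenFit | None = None
    if np.allclose(ratio.to_numpy(), threshold):
        # flat exactly at the threshold: report the first year, flagged
        crossing = int(years[0])
        degenerate = True
    elif len(ratio) >= 3:
        ts_fit = theil_sen(years, ratio.to_numpy())
        if ts_fit.slope != 0:
            y_star = (threshold - ts_fit.intercept) / ts_fit.slope
            start_val = ts_fit.intercept + ts_fit.slope * years[0]
            moving_toward = (start_val - threshold) * ts_fit.slope < 0
            if moving_toward and years[0] <= y_star <= years[-1] + horizon_years:
                crossing = int(np.ceil(y_star - 1e-9))
    return RegimeDiagnostic(
        region_id=no2.region_id,
        annual_ratio=ratio,
        threshold=threshold,
        crossing_year=crossing,
        degenerate=degenerate,
        trend=ts_fit,
    )
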