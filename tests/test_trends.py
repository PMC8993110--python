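import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from citytrends import (
    InsufficientCoverageError,
    SyntheticScenario,
    fit_seasonal_trend,
    monthly_truth,
    ozone_regime,
    relative_trend,
    theil_sen,
)
from conftest import make_series


def series_from_scenario(scen, region_id="r", species="NO2", seed=None):
    """Monthly series straight from scenario truth (+ optional noise/gaps)."""
    import citytrends.synthetic as syn

    rng = np.random.default_rng(scen.seed if seed is None else seed)
    frame = syn.monthly_means(scen, rng)
    vals = [
        (m, 2) if gap else m for m, gap in zip(frame["mean"], frame["gap"])
    ]
    return make_series(vals, start=f"{scen.years[0]}-01",
                       region_id=region_id, species=species)


def brute_force_theil_sen(years, values):
    """Independent all-pairs oracle: median of pairwise slopes."""
    years = np.asarray(years, float)
    values = np.asarray(values, float)
    slopes = [
        (values[j] - values[i]) / (years[j] - years[i])
        for i in range(len(years))
        for j in range(i + 1, len(years))
    ]
    return float(np.median(slopes))


class TestSeasonalFit:
    def test_noiseless_recovery_to_machine_precision(self):
        scen = SyntheticScenario(
            baseline_column=2.0, rel_trend=0.05, seasonal_amplitude=0.2,
            seasonal_phase=3.0, noise_sd=0.0, gap_prob=0.0, years=(2005, 2018),
        )
        fit = fit_seasonal_trend(series_from_scenario(scen))
        assert fit.rel_trend == pytest.approx(5.0, abs=1e-6)
        assert fit.mu0 == pytest.approx(2.0, rel=1e-9)
        assert fit.amp == pytest.approx(0.2 * 2.0, rel=1e-6)
        assert fit.phase == pytest.approx(3.0, abs=1e-6)
        assert fit.significant

    def test_constant_series_has_zero_insignificant_trend(self):
        fit = fit_seasonal_trend(make_series([4.0] * 60))
        assert fit.beta == pytest.approx(0.0, abs=1e-12)
        assert not fit.significant

    def test_coverage_gate_refuses_40_of_168_months(self):
        vals = [1.0 if i < 40 else None for i in range(168)]
        series = make_series(vals)
        assert series.n_retained == 40
        with pytest.raises(InsufficientCoverageError, match="insufficient"):
            fit_seasonal_trend(series)

    def test_gate_passes_just_above_30_percent(self):
        vals = [1.0 + 0.01 * i if i < 55 else None for i in range(168)]
        fit = fit_seasonal_trend(make_series(vals))
        assert fit.coverage_fraction == pytest.approx(55 / 168)

    def test_adding_annual_sinusoid_leaves_beta_unchanged(self):
        t = np.arange(168) / 12.0
        base = 3.0 + 0.12 * t
        fit_plain = fit_seasonal_trend(make_series(base))
        for phase in (0.0, 1.2, 4.5):
            wavy = base + 0.8 * np.sin(2 * np.pi * t + phase)
            fit_wavy = fit_seasonal_trend(make_series(wavy))
            assert fit_wavy.beta == pytest.approx(fit_plain.beta, abs=1e-8)

    def test_annual_mean_matches_monthly_average_of_fitted_curve(self):
        scen = SyntheticScenario(
            baseline_column=1.0, rel_trend=0.03, seasonal_amplitude=0.2,
            years=(2005, 2018),
        )
        fit = fit_seasonal_trend(series_from_scenario(scen))
        t = np.arange(12) / 12.0 + 5.0  # year 2010
        assert fit.annual_mean(2010) == pytest.approx(fit.predict_t(t).mean())
        with pytest.raises(ValueError, match="outside record"):
            fit.annual_mean(2030)

    def test_bootstrap_ci_close_to_covariance_ci(self):
        scen = SyntheticScenario(
            rel_trend=0.05, seasonal_amplitude=0.15, noise_sd=0.08,
            years=(2005, 2018), seed=12,
        )
        series = series_from_scenario(scen)
        cov_fit = fit_seasonal_trend(series, ci_method="covariance")
        boot_fit = fit_seasonal_trend(series, ci_method="bootstrap",
                                      n_boot=300, seed=1)
        cov_w = cov_fit.beta_ci[1] - cov_fit.beta_ci[0]
        boot_w = boot_fit.beta_ci[1] - boot_fit.beta_ci[0]
        assert boot_w == pytest.approx(cov_w, rel=0.6)

    def test_month_removal_robustness(self):
        """Dropping a random 20% of months moves rel_trend by less than the
        CI half-width in at least 90% of replicates."""
        scen = SyntheticScenario(
            rel_trend=0.04, seasonal_amplitude=0.15, noise_sd=0.1,
            years=(2005, 2018),
        )
        rng = np.random.default_rng(99)
        ok = 0
        n_rep = 50
        for _ in range(n_rep):
            frame = monthly_truth(scen)
            vals = frame["mean"].to_numpy() + rng.normal(0, 0.1, len(frame))
            full = make_series(vals)
            fit_full = fit_seasonal_trend(full)
            drop = rng.choice(len(vals), size=len(vals) // 5, replace=False)
            masked = [None if i in set(drop) else vals[i] for i in range(len(vals))]
            fit_sub = fit_seasonal_trend(make_series(masked))
            half_width = (fit_full.beta_ci[1] - fit_full.beta_ci[0]) / 2.0
            rel_shift = abs(fit_sub.rel_trend - fit_full.rel_trend)
            if rel_shift < 100.0 * half_width / fit_full.mu0:
                ok += 1
        assert ok >= 0.9 * n_rep


class TestTheilSen:
    def test_exact_line(self):
        fit = theil_sen([2005, 2006, 2007], [1.0, 2.0, 3.0])
        assert fit.slope == pytest.approx(1.0)

    def test_median_of_pairwise_slopes(self):
        # pairwise slopes {1, 5, 9} -> median 5
        fit = theil_sen([0, 1, 2], [0.0, 1.0, 10.0])
        assert fit.slope == pytest.approx(5.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        years = np.arange(2005, 2019, dtype=float)
        vals = rng.normal(0, 1, len(years))
        order = rng.permutation(len(years))
        a = theil_sen(years, vals)
        b = theil_sen(years[order], vals[order])
        assert a.slope == b.slope

    def test_duplicate_years_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            theil_sen([2005, 2005, 2006], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            theil_sen([2005, 2006], [1.0, 2.0])

    @given(
        n=st.integers(3, 50),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        years = np.arange(n, dtype=float)
        vals = rng.normal(0, 5, n)
        assert theil_sen(years, vals).slope == pytest.approx(
            brute_force_theil_sen(years, vals), abs=1e-12
        )


class TestRelativeTrend:
    @pytest.mark.parametrize(
        "slope,baseline,expected",
        [(0.5, 10.0, 5.0), (0.0, 7.0, 0.0), (-0.2, 10.0, -2.0)],
    )
    def test_percent_per_year(self, slope, baseline, expected):
        fit = theil_sen([0, 1, 2], [0.0, slope, 2 * slope])
        assert relative_trend(fit, baseline) == pytest.approx(expected)

    def test_nonpositive_baseline_rejected(self):
        fit = theil_sen([0, 1, 2], [0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="baseline"):
            relative_trend(fit, 0.0)


class TestOzoneRegime:
    def _ratio_series(self, annual_ratios, start=2005):
        """HCHO/NO2 pair with NO2 == 1 so the ratio equals the HCHO value."""
        months_h, months_n = [], []
        for r in annual_ratios:
            months_h += [float(r)] * 12
            months_n += [1.0] * 12
        hcho = make_series(months_h, start=f"{start}-01", species="HCHO")
        no2 = make_series(months_n, start=f"{start}-01", species="NO2")
        return hcho, no2

    def test_high_constant_ratio_never_crosses(self):
        hcho, no2 = self._ratio_series([23.0] * 5)
        diag = ozone_regime(hcho, no2)
        assert diag.crossing_year is None
        np.testing.assert_allclose(diag.annual_ratio, 23.0)

    def test_declining_ratio_crosses_in_third_year(self):
        hcho, no2 = self._ratio_series([4.0, 3.0, 2.0], start=2005)
        diag = ozone_regime(hcho, no2)
        assert diag.crossing_year == 2007

    def test_extrapolated_crossing_beyond_record(self):
        hcho, no2 = self._ratio_series([5.0, 4.5, 4.0, 3.5], start=2005)
        diag = ozone_regime(hcho, no2)  # slope -0.5/yr from 5: crosses at +6y
        assert diag.crossing_year == 2011

    def test_flat_ratio_at_threshold_is_degenerate(self):
        hcho, no2 = self._ratio_series([2.0] * 4, start=2005)
        diag = ozone_regime(hcho, no2)
        assert diag.crossing_year == 2005
        assert diag.degenerate

    def test_nonpositive_no2_year_omitted_with_warning(self):
        hcho = make_series([4.0] * 36, species="HCHO")
        no2 = make_series([1.0] * 12 + [-1.0] * 12 + [1.0] * 12, species="NO2")
        with pytest.warns(UserWarning, match="non-positive"):
            diag = ozone_regime(hcho, no2)
        assert list(diag.annual_ratio.index) == [2005, 2007]
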