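"""Parameter-recovery and self-consistency studies on synthetic ensembles.

These run the package end-to-end against its own generator truth: seasonal
trend recovery with CI calibration, Theil-Sen agreement with a brute-force
all-pairs oracle, partition reconstruction and sign recovery, the mortality
decomposition identity, and demo-run determinism. Each takes an explicit
seed and returns plain scalars so it can back both the test suite and the
reproduction script.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np

from . import health, pipeline, synthetic, trends
from .attribution import partition, partition_trends
from .sampling import MonthlyCitySeries
from .synthetic import SyntheticScenario, monthly_means


def _series_from_frame(frame, region_id="r", species="NO2") -> MonthlyCitySeries:
    import pandas as pd

    n = np.where(frame["gap"].to_numpy(), 2, 10)
    data = pd.DataFrame(
        {
            "year": frame["year"],
            "month": frame["month"],
            "mean": frame["mean"],
            "n_pixels": n,
            "retained": n >= 5,
        }
    )
    return MonthlyCitySeries(region_id, species, data)


def trend_recovery_ensemble(
    n_reps: int = 200,
    seed: int = 0,
    rel_trend_range: tuple[float, float] = (-0.10, 0.10),
    noise_sd: float = 0.10,
    gap_prob: float = 0.20,
) -> dict:
    """Seasonal-fit recovery over an ensemble of synthetic city records.

    Returns the mean bias of the recovered relative trend (percent per
    year), the fraction of replicates whose 95% CI on the absolute trend
    covers the truth, and the fraction where the truth lies inside the
    replicate's own CI on the relative scale.
    """
    rng = np.random.default_rng(seed)
    errors = np.empty(n_reps)
    covered = np.zeros(n_reps, bool)
    for i in range(n_reps):
        r = rng.uniform(*rel_trend_range)
        scen = SyntheticScenario(
            baseline_column=1.0,
            rel_trend=r,
            seasonal_amplitude=0.15,
            seasonal_phase=float(rng.uniform(0, 12)),
            noise_sd=noise_sd,
            gap_prob=gap_prob,
            years=(2005, 2018),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        series = _series_from_frame(monthly_means(scen))
        fit = trends.fit_seasonal_trend(series)
        errors[i] = fit.rel_trend - 100.0 * r
        beta_true = scen.baseline_column * r
        covered[i] = fit.beta_ci[0] <= beta_true <= fit.beta_ci[1]
    return {
        "bias_pct_per_year": float(errors.mean()),
        "rmse_pct_per_year": float(np.sqrt((errors**2).mean())),
        "ci_coverage_pct": float(100.0 * covered.mean()),
        "n": n_reps,
    }


def theil_sen_oracle_check(n_instances: int = 1000, seed: int = 0) -> dict:
    """Exact agreement of the Theil-Sen slope with the all-pairs median."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    mismatches = 0
    for _ in range(n_instances):
        n = int(rng.integers(3, 51))
        x = np.arange(n, dtype=float)
        y = rng.normal(0.0, rng.uniform(0.5, 10.0), n)
        fit = trends.theil_sen(x, y)
        i, j = np.triu_indices(n, k=1)
        oracle = float(np.median((y[j] - y[i]) / (x[j] - x[i])))
        diff = abs(fit.slope - oracle)
        max_diff = max(max_diff, diff)
        mismatches += diff != 0.0
    return {"max_abs_diff": max_diff, "n_mismatch": int(mismatches),
            "n": n_instances}


def partition_recovery_ensemble(n_series: int = 100, seed: int = 0) -> dict:
    """Reconstruction error and noise-free trend-sign recovery.

    Reconstruction: for every burning-season month above its year's 75th
    percentile, excess + anthropogenic annual mean must reproduce the
    monthly value (machine precision). Sign recovery: on noise-free series
    the Theil-Sen signs of the burning and anthropogenic annual trends must
    match the generator's (bb_trend, rel_trend) signs.
    """
    rng = np.random.default_rng(seed)
    bb = frozenset({12, 1, 2, 3})
    max_rel_err = 0.0
    signs_ok = 0
    n_checked = 0
    for _ in range(n_series):
        scen = SyntheticScenario(
            baseline_column=float(rng.uniform(0.5, 10.0)),
            rel_trend=float(rng.uniform(-0.10, 0.10)),
            seasonal_amplitude=0.0,
            bb_months=bb,
            bb_excess=float(rng.uniform(0.2, 0.8)),
            bb_trend=float(rng.uniform(-0.10, 0.10)),
            noise_sd=0.0,
            gap_prob=0.0,
            years=(2005, 2018),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        series = _series_from_frame(monthly_means(scen))
        part = partition(series, bb)
        for rec in part.bb_excess.itertuples(index=False):
            recon = rec.excess + part.anth_annual_mean[rec.year]
            max_rel_err = max(max_rel_err, abs(recon - rec.value) / abs(rec.value))
        bb_fit, anth_fit = partition_trends(part)
        n_checked += 1
        if (
            np.sign(bb_fit.slope) == np.sign(scen.bb_trend)
            and np.sign(anth_fit.slope) == np.sign(scen.rel_trend)
        ):
            signs_ok += 1
    return {
        "max_reconstruction_rel_error": max_rel_err,
        "sign_recovery_pct": 100.0 * signs_ok / n_checked,
        "n": n_series,
    }


def decomposition_identity_check(n: int = 100, seed: int = 0) -> dict:
    """Max |sum of factor log-ratios - ln(M_start/M_end)| on random inputs."""
    rng = np.random.default_rng(seed)
    crf = health.CRFSpec()
    worst = 0.0
    for _ in range(n):
        def draw():
            return {
                "pm25": float(rng.uniform(10, 120)),
                "population": float(rng.uniform(1e5, 2e7)),
                "frac_over14": float(rng.uniform(0.4, 0.9)),
                "y0": float(rng.uniform(0.003, 0.02)),
            }
        a, b = draw(), draw()
        b["frac_over14"] = a["frac_over14"]  # travels with the population factor
        dec = health.decompose_factors(a, b, crf)

        def deaths(x):
            af = health.attributable_fraction(x["pm25"], crf)["central"]
            return x["population"] * x["frac_over14"] * x["y0"] * af

        residual = abs(dec.total - np.log(deaths(a) / deaths(b)))
        worst = max(worst, residual)
    return {"max_identity_residual": worst, "n": n}


def demo_determinism_check(workdir, seed: int = 0) -> dict:
    """Run the bundled three-city demo twice; hash-compare all outputs."""
    workdir = Path(workdir)

    def run(tag):
        cfg = pipeline.demo_config(workdir / tag, seed=seed)
        pipeline.run_pipeline(cfg)
        return {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted((workdir / tag).glob("*.csv"))
        }

    first, second = run("run1"), run("run2")
    return {
        "identical": first == second,
        "n_outputs": len(first),
    }
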