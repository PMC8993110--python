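"""Population-exposure trends: E_pop = N x annual mean of the fitted proxy,
evaluated at record start and end for PM2.5 (AOD) and NO2."""

from common import RUN_DIR, get_config
from citytrends.pipeline import _read_csv, _stage_exposure


def main():
    config = get_config()
    _stage_exposure(config, RUN_DIR)
    exp = _read_csv(RUN_DIR / "exposure.csv")
    print("population exposure trends (% of start value per year):")
    for rec in exp.itertuples(index=False):
        if rec.status != "ok":
            print(f"  {rec.region_id:8s} {rec.species}: {rec.status}")
            continue
        print(f"  {rec.region_id:8s} {rec.species:4s} "
              f"{rec.rel_exposure_trend_pct:+5.2f} %/a")


if __name__ == "__main__":
    main()
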