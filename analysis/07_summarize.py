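"""Collect all stage outputs into per-city summary tables under results/."""

from common import RESULTS, RUN_DIR, get_config
from citytrends import summarize


def main():
    config = get_config()
    tables = summarize(RUN_DIR)
    for name, df in tables.items():
        path = RESULTS / f"summary_{name}.csv"
        df.to_csv(path, index=False)
        print(f"wrote {path} ({len(df)} rows)")
    print()
    print(tables["mortality_summary"].round(1).to_string(index=False))


if __name__ == "__main__":
    main()
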