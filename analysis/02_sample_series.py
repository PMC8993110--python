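"""Sample pixels into city-wide monthly-mean series.

Applies QA filtering, the buffered point-in-domain test and the 5-pixel
retention rule; subtracts the fitted ocean background from HCHO to isolate
the reactive-NMVOC component.
"""

import pandas as pd

from common import RUN_DIR, get_config
from citytrends.pipeline import _stage_sample


def main():
    config = get_config()
    outputs = _stage_sample(config, RUN_DIR)
    print(f"wrote {len(outputs)} monthly series")
    for name in outputs:
        df = pd.read_csv(RUN_DIR / name)
        kept = df["retained"].sum()
        print(f"  {name}: {kept}/{len(df)} months retained")


if __name__ == "__main__":
    main()
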