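import numpy as np
import pandas as pd
import pytest

from citytrends import MonthlyCitySeries, square_region


def make_series(
    values,
    start="2005-01",
    region_id="r",
    species="NO2",
    n_pixels=10,
):
    """Build a MonthlyCitySeries from explicit monthly values.

    ``values`` may contain None/NaN for months with no data (n_pixels 0) or
    (value, n) tuples to control the pixel count.
    """
    periods = pd.period_range(start, periods=len(values), freq="M")
    means, counts = [], []
    for v in values:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            means.append(np.nan)
            counts.append(0)
        elif isinstance(v, tuple):
            means.append(v[0])
            counts.append(v[1])
        else:
            means.append(float(v))
            counts.append(n_pixels)
    data = pd.DataFrame(
        {
            "year": periods.year,
            "month": periods.month,
            "mean": means,
            "n_pixels": counts,
            "retained": [c >= 5 for c in counts],
        }
    )
    return MonthlyCitySeries(region_id, species, data)


@pytest.fixture
def city_region():
    """0.3-degree square city with a 6.5 km sampling buffer."""
    return square_region("testville", 10.0, 5.0, 0.3, buffer_km=6.5)


@pytest.fixture
def unbuffered_region():
    return square_region("testville", 10.0, 5.0, 0.3, buffer_km=0.0)
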