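# citytrends

Trend analysis of satellite air-quality records over fast-growing tropical
cities, and the health burden those trends imply.

Many rapidly urbanizing cities in tropical Africa, the Middle East and Asia
lack ground monitoring, but long space-based records of tropospheric NO2,
total-column HCHO (a proxy for reactive non-methane VOCs after background
removal), NH3 and aerosol optical depth (AOD, a proxy for surface PM2.5)
constrain how their air quality is changing. `citytrends` implements the
full analysis chain for such records, exercisable end-to-end on synthetic
data with known ground truth:

1. **City sampling** — pixel centres falling in a buffered city polygon,
   QA filtering, unweighted monthly means, ≥ 5 pixels per retained month;
   ocean-background subtraction for the reactive HCHO component; rural
   reference boxes; area-weighted sampling of gridded annual fields.
2. **Trend fitting** — the seasonal model
   `f(t) = mu0 + beta·t + amp·sin(2πt + phase)` fit to retained months by
   least squares, with a > 30% temporal-coverage gate, 95% CIs on `beta`,
   and relative trends in % of the record-start baseline per year;
   Theil-Sen median trends for annual series; HCHO/NO2 ozone-regime
   diagnostics with threshold-crossing projection.
3. **Source partitioning** — per-year 75th-percentile split into
   biomass-burning excess and anthropogenic (non-burning) components,
   trends of both, and direction consistency against satellite burned
   fraction.
4. **Exposure & health** — population exposure E_pop = N·C; absolute PM2.5
   by anchoring the fitted AOD record at a modelled midpoint concentration;
   attributable fraction AF = 1 − 1/RR(c) with a configurable
   concentration-response function; premature deaths
   `pop × frac≥14 × y0 × AF`; and a log-ratio decomposition of the change
   in deaths into PM2.5, population and baseline-mortality contributions.

The synthetic generator (`citytrends.synthetic`) is first-class, tested
code: it emulates tropical seasonality, linear relative trends,
burning-season spikes, cloud-gap missingness and demographic growth, so
every downstream stage is testable by parameter recovery. See
`docs/methods.md` for the models, conventions and limitations.

## Worked example

The bundled three-city demo runs all seven stages (synthesize → sample →
fit → partition → exposure → health → decompose) in a few seconds:

```python
import citytrends as ct

config = ct.demo_config("results/run", seed=0)
manifest = ct.run_pipeline(config)
tables = ct.summarize("results/run")
print(tables["mortality_summary"].round(1).to_string(index=False))
```

```
region_id  pm25_2005  pm25_2018  deaths_2005  deaths_2018  change
    alpha       35.3       44.0      10148.9      15135.3  4986.4
     beta       52.1       85.4      22373.0      38858.8 16485.8
    gamma       33.8       36.0       9452.2      12731.3  3279.2
```

City `beta` (a South-Asian archetype generated with a +5 %/a AOD trend)
sees PM2.5 rise from 52.1 to 85.4 μg m⁻³ between 2005 and 2018, and
attributable deaths rise 74% — driven, per the log-ratio decomposition in
`tables["decomposition"]`, roughly equally by the PM2.5 increase and
population growth. City `alpha`'s decline in baseline mortality offsets
part of its growth; absolute death counts depend on the configurable
concentration-response coefficients (the defaults are illustrative).

The same steps can be run as numbered drivers, each printing what it found
and writing its tables under `results/`:

```
cd analysis
python 01_simulate.py      # synthetic pixels, burned fraction, demographics
python 02_sample_series.py # monthly city series + reactive HCHO
python 03_fit_trends.py    # seasonal fits, ozone-regime diagnostics
python 04_partition_sources.py
python 05_exposure.py
python 06_mortality.py
python 07_summarize.py
```

For example, `03_fit_trends.py` reports per-city relative trends with
significance stars (`alpha NO2 +3.30* %/a` against a generator truth of
+4 %/a overall including its declining burning component), and
`04_partition_sources.py` shows the partition isolating the anthropogenic
trend from burning-season spikes.

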