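# Methods

`citytrends` implements a city-scale trend-analysis chain for satellite
column records of short-lived air pollutants (tropospheric NO2, total-column
HCHO as a reactive-NMVOC proxy, NH3, and AOD as a surface-PM2.5 proxy),
followed by population-exposure and PM2.5 health-burden estimation. This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic test bed does and does not establish.

## City sampling

A pixel-level observation is (lon, lat, time, value, qa_pass). QA flags are
computed upstream (cloud fraction, terrain reflectivity, solar zenith angle
and product-specific filters are outside scope); a pixel with
`qa_pass = False` never enters any mean. A pixel contributes to a city
month iff its footprint centre lies inside the city polygon dilated by a
metric buffer matched to the instrument footprint (default 6.5 km for
UV-vis/AOD-class pixels, 10 km for IR sounders; 0 disables buffering).
Buffering is performed in a local azimuthal equidistant projection about
the region centroid so the buffer distance is kilometres at any latitude;
degree-based buffering would distort poleward. The point-in-domain test is
inclusive of the boundary (the convention is arbitrary; it is documented
and tested). Monthly means are unweighted arithmetic means in UTC calendar
months; months with fewer than 5 usable pixels are kept in the series but
flagged unretained and excluded from all fits.

The reactive-NMVOC proxy subtracts, month by month, the *fitted* seasonal
background column (from a remote ocean domain spanning the city's latitude
range) from the city HCHO series. Subtracting the fit rather than the raw
ocean means removes the slowly varying methane-oxidation background without
injecting the ocean record's sampling noise, and keeps city months the
ocean record misses. Negative residuals are expected near the detection
limit; they are retained and flagged, never truncated. A rural 0.2° × 0.2°
reference box, placed at an explicit bearing 50–100 km from the city
centroid, provides the biogenic-VOC control series.

Gridded annual fields (burned fraction, emissions) are sampled over the
same buffered extent. Cells are weighted by the fraction of their area
overlapping the domain; `mean` mode (burned fraction) additionally weights
by cos(latitude) cell area, `sum` mode (emissions) attributes each cell's
total in proportion to its overlap fraction.

## Seasonal-trend model

Monthly series are fit with

    f(t) = mu0 + beta * t + amp * sin(2*pi*t + phase),    t in years,

i.e. a record-start baseline, a linear trend and one annual harmonic with
free amplitude and phase. Because `amp*sin(2*pi*t + phase)` expands to
`a*sin(2*pi*t) + b*cos(2*pi*t)`, the model is linear in its parameters and
is fit by ordinary least squares on the retained months; the 95% CI on
`beta` uses the exact parameter covariance and a Student-t critical value.
An optional semi-annual harmonic (`harmonics=2`) and a block-bootstrap CI
(resampling whole calendar years, percentile bounds) are available; on
well-behaved series the two CI methods agree closely. One annual harmonic
is the smallest model that captures the pronounced tropical seasonality
(monsoon washout, dry-season accumulation, burning seasons); adding any
pure 1-year sinusoid to a series leaves `beta` unchanged, which is tested
to 1e-8.

A fit is refused below the temporal-coverage gate: retained months must
exceed 30% of the record (> 50 of 168 months for a 2005–2018 monthly
record, > 40 of 132 for 2008–2018). Refusals surface as an explicit
"insufficient coverage" status, not as silent NaNs. Trends are significant
at 95% when the CI on `beta` excludes zero; a numerical floor (1e-10 of the
data scale) prevents an exactly interpolated series — zero residual
variance, `beta` at machine epsilon — from being declared significant.
Relative trends are reported as percent of the record-start *fitted*
baseline per year (100·beta/mu0), which is robust to missing early months,
and baselines for display are `mu0` itself.

Annual series (partition components, burned fraction, emissions, HCHO/NO2
ratios) are trended with the Theil-Sen median-of-pairwise-slopes estimator
(scipy's implementation; the rank-based 95% CI), which resists the large
interannual variability of burning-driven records. It is checked exactly
against a brute-force all-pairs oracle.

The ozone-regime diagnostic forms, per year, the ratio of annual-mean total
HCHO to annual-mean NO2 over months retained in both records (years with a
non-positive NO2 mean are dropped with a warning). Ratios above 2 indicate
NOx-sensitive ozone production. The Theil-Sen line through the annual
ratios is extrapolated to the threshold; a crossing year is reported only
when the line actually moves toward and reaches the threshold within a
20-year horizon past the record end, and a flat ratio sitting exactly on
the threshold is reported as the first year, flagged degenerate.

## Source partitioning

Within each calendar year (≥ 8 retained months; fewer makes a 75th
percentile meaningless and the year is skipped), the monthly means are
split at the year's 75th percentile, computed with linear interpolation
between order statistics (NumPy's default, "type 7"); months exactly equal
to the percentile classify as anthropogenic. The anthropogenic level is the
annual mean of the at-or-below months; the biomass-burning excess of an
above-percentile month *within the prescribed burning season* is its value
minus that level, so excess + anthropogenic level reconstructs the monthly
mean (to one ulp). Burning-season calendars ship as editable config:
Dec–Mar (northern Africa), Jul–Nov (southern Africa), Jan–Apr (South Asia
and mainland Southeast Asia), Aug–Oct (equatorial Southeast Asia). A city
counts as burning-influenced when, in at least half its partitioned years,
every above-percentile month falls inside the prescribed season.

Annualized series — per-year mean of monthly excess on the burning side,
the annual anthropogenic mean on the other — are trended by Theil-Sen
(≥ 3 years each; an identically flat series has an empty excess set and a
burning trend of exactly zero). Direction agreement with the burned-fraction
trend is `consistent`/`opposite` only when both CIs exclude zero, else
`indeterminate`.

## Exposure and health burden

Population exposure is E_pop = N·C with N the city population and C the
annual mean of the fitted proxy curve — deliberately a pseudo-exposure in
column/AOD units, since the proxies' *trends*, not their absolute values,
carry the information. Exposure trends are percent of the record-start
value per year, and compose additively to first order from the population
and concentration trends (+1.3 %/a population and +0.5 %/a concentration
give +1.8 %/a exposure); the multiplicative cross-term is reported
separately and is negligible at single-digit annual rates.

Absolute PM2.5 anchors the fitted AOD curve at a modelled concentration for
the record midpoint: PM2.5(y) = anchor · C_fit(y)/C_fit(anchor year).
Scaling the anchor by x scales every year by x exactly, so anchor
uncertainty propagates transparently.

The attributable fraction is AF(c) = 1 − 1/RR(c) with a pluggable
piecewise log-linear relative risk RR(c) = exp(β(c)·(c − c0)) above a
counterfactual c0 (default 4.5 μg m⁻³), β(c) interpolated from a
concentration-grid table with central/low/high rows driving the 95% band.
The default table — about an 8% all-cause risk increase per 10 μg m⁻³
below 50 μg m⁻³, attenuating above, with a much wider band at high
concentrations — is **illustrative**: it reproduces the qualitative shape
of modern meta-analytic risk functions (sub-linear at high PM2.5, large
high-concentration uncertainty) but absolute death counts are meaningful
only with coefficients supplied by the user. Each CRF variant is validated
non-decreasing in concentration at construction. Deaths are
population × fraction over 14 × all-cause baseline mortality rate × AF,
summed over strata when several are given; the default demographic model
carries a single ≥ 14-year stratum.

The change in deaths between record start and end is decomposed into
PM2.5, population and baseline-mortality contributions by log-ratios: for
each factor, ln(deaths with that factor at start-year values and the others
at end-year values / deaths with everything at end-year values). The
population factor carries the over-14 fraction with it. Because the death
model is multiplicative, the three log-ratios sum to ln(M_start/M_end)
exactly (tested to 1e-12). Per-year averages of the 2005–2018 change divide
by the 14-year observing period (inclusive year count), so a 180,000 total
increase averages 13,000 a⁻¹.

## Synthetic test bed

The generator writes pixel tables whose within-month values average
*exactly* to the scenario's monthly mean (scatter is mean-centred), with
the monthly mean = baseline·(1 + rel_trend·t + seasonal sinusoid +
burning-season excess·(1 + bb_trend·t)) + Gaussian noise. Gap months emit
fewer than 5 usable pixels; a small fraction of QA-failing pixels with
perturbed values exercises filtering. Burned fraction is generated on a
0.25° grid with a fixed seeded spatial pattern and a temporal scale
following the burning trend; demographics compound at a constant growth
rate. Truth model and fitting model coincide by design (linear relative
trend, one annual harmonic), which makes noise-free recovery exact to
machine precision and CI calibration interpretable: on 200 replicates with
10%-of-baseline noise and 20% gap months, the recovered relative trend is
unbiased to better than 0.1 %/a and the 95% CI covers the truth at close to
its nominal rate.

What this does **not** show about real records: retrieval biases and
spatially correlated errors, drifting instrument sensitivity, seasonality
that changes shape over time, multiplicative (rather than additive) noise
— a multiplicative mode exists but is off by default — free-tropospheric
background changes, and any mismatch between column trends and surface
trends. Those belong to the data products and validation studies, not to
this statistical chain.

Default study conditions: 14-year monthly records (2005–2018), ~8–15
usable pixels per retained month, noise 5–10% of baseline, gap probability
0.1–0.2, burning-season excesses of 15–30% of baseline. The bundled
three-city demo (coastal West Africa / South Asia / equatorial Southeast
Asia archetypes) runs all seven stages in a few seconds; ensemble sizes in
the tests (200 trend replicates, 1000 Theil-Sen instances, 100 partition
series) keep the full suite under a minute while leaving binomial tolerances
meaningful.

## Known limitations

- The CRF defaults are illustrative (above); mortality CIs reflect only CRF
  uncertainty, not anchor-PM2.5 or demographic uncertainty.
- Ocean-background and rural-reference placement is explicit (offsets,
  bearings) rather than optimized against coastline or land-cover masks.
- Cell-overlap weights for gridded sampling are computed in degree space
  (with cos-latitude area weighting in mean mode); exact spherical overlap
  is unnecessary at 0.25–0.5° cell sizes but would matter for very large
  cells at high latitude.
- `partition` assumes the burning season is the only systematic cause of
  above-percentile months; strong non-burning episodes (dust outbreaks)
  will fail the overlap check and exclude a city rather than be attributed.
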