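# heatmort

Heat-related mortality attribution for county-level daily temperature and
all-cause death-count data.

Official death-certificate tallies are known to undercount deaths in which
heat was a contributing rather than primary cause. `heatmort` implements the
population-level statistical alternative: a minimum-mortality-temperature
exposure framework that converts a region's daily mean temperature series
and daily death counts into annual heat-attributable death estimates, under
three complementary definitions, and compares them against official annual
counts. It is aimed at environmental-epidemiology and climate-health
analysts working with long-format regional (e.g., county) panels.

## The model

For each region *c*:

- **OT** (optimal temperature, a.k.a. minimum-mortality temperature): the
  84th percentile of daily mean temperature over a reference window
  (default 2010–2023).
- **SMT**: the June–September mean temperature over the same window.
- **Relative risk** above OT is a quadratic in the temperature excess,
  with coefficients that are affine in SMT so cooler climates get steeper
  curves:

  RR(T) = 1 + A(SMT)·(T − OT)² + B(SMT)·(T − OT)  for T > OT, else 1,

  floored at 1 (heat branch only).
- **MMTD(y)**: the baseline death rate, estimated as the mean daily death
  count on days within ±2 °C of OT, per year over a fit window (default
  2013–2019, excluding pandemic years) and linearly extrapolated outside
  it.
- **Daily attributable deaths**: HRD = (RR(T) − 1) · MMTD(y) on summer
  (June–September) days.

Three estimators aggregate daily HRD to annual, per-region and state
totals:

| Estimator | Definition |
|---|---|
| **OTM** (optimal temperature method) | sum of HRD over summer days with T > OT |
| **XHM** (extreme heat method) | the same sum restricted to days with T ≥ the 95th-percentile temperature |
| **EDM** (excess death method) | OTM minus the mean annual OTM under the climate of a historical baseline window (default 1950–1963), evaluated with the current climatology and a fixed study-period reference MMTD |

OTM − XHM is the contribution of *moderate* heat (between the 84th and
95th percentiles); EDM isolates the contribution of climate change since
the baseline period.

Because the real study inputs (gridded reanalysis temperature, restricted
state mortality records) are not shippable, the package includes a
synthetic-data module that generates county-like scenarios — seasonal
cycle, AR(1) weather noise, optional warming trend, Poisson death counts
with mean MMTD_true·RR_true(T), and under-reported "official" counts —
with every ground truth known, plus an analytic oracle for the expected
value of each estimator.

## Worked example

```python
import heatmort as hm

cfg = hm.ScenarioConfig(n_regions=3, years=(2010, 2023), seed=42)
temps = hm.generate_temperature(cfg)
deaths = hm.generate_mortality(temps, cfg)

model = hm.HeatAttributionModel()
model.fit(temps, deaths)          # climatology + MMTD + OTM/XHM
model.add_edm(temps)              # EDM with the study window as baseline

print(model.climatology_.climatology_.round(2))
print(model.hrd_table_.query("scope == 'state'").round(1).to_string(index=False))
```

prints

```
              OT    SMT    P95  n_days
region_id
R00        26.77  26.55  29.21    5113
R01        27.82  27.68  30.22    5113
R02        28.97  28.73  31.29    5113
scope  year   otm   xhm    edm
state  2010 201.0 113.8 -105.3
state  2011 178.0  98.8 -128.4
...
state  2021 463.1 342.9  156.8
state  2022 412.1 291.0  105.7
state  2023 266.7 149.8  -39.7
```

Each `otm` value is the expected annual death count attributable to any
above-optimal heat in that three-region synthetic state; `xhm` is the part
occurring on extreme (≥95th-percentile) days; `edm` is the annual excess
relative to the period-mean climate — negative in years cooler than the
baseline mean, and averaging ≈ 0 here because the baseline *is* the study
window. The same workflow runs from the shell via the `heatmort` CLI
(`simulate`, `climatology`, `mmtd`, `estimate`, `report`,
`verify-reference`).

The package also ships the published statewide Texas annual estimates for
2010–2023 (`heatmort.load_reference_table()`), whose summary statistics —
15,826 total OTM deaths (1,130/yr), 3,470 XHM deaths (248/yr), a 6.15
OTM-to-official ratio, and a ~78% moderate-heat share — are reproduced by
the reporting layer and checked by `heatmort verify-reference`.

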