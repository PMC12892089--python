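# Methods

## Exposure–mortality model

The package attributes deaths to heat through a minimum-mortality-
temperature (MMT) framework. The central assumptions are:

1. Each region has an optimal temperature OT at which daily mortality is
   lowest; mortality risk rises monotonically above it. OT is
   operationalized as the 84th percentile of daily mean temperature over
   a reference window, a common empirical proxy for the MMT in US
   settings.
2. Relative risk above OT is a quadratic in the temperature excess
   ΔT = T − OT, RR = 1 + A·ΔT² + B·ΔT, with A and B affine functions of
   the region's summer mean temperature (SMT). The SMT parameterization
   encodes the observation that cooler climates show steeper
   heat–mortality slopes (less acclimatization); it makes a single
   coefficient file applicable across a climatically diverse set of
   regions.
3. Only the heat branch is modelled: RR ≡ 1 at and below OT, and the
   curve is floored at 1 above OT, so attributable deaths are never
   negative. Cold-related mortality, lag structures, and demographic
   stratification are out of scope.
4. Daily attributable deaths factorize as HRD = (RR(T) − 1) · MMTD(y),
   where MMTD(y) is the year's baseline death rate near OT. This treats
   the baseline as temperature-independent within a year and risk as
   multiplicative on it.

Attribution is computed for June–September ("summertime") days only.

## Estimators

- **OTM** sums HRD over summer days with T > OT (strict inequality;
  boundary days are measure-zero for continuous temperatures but the
  convention is fixed).
- **XHM** restricts the sum to days with T ≥ the region's 95th-percentile
  temperature (inclusive).
- **EDM** subtracts, from each study year's OTM, a single constant: the
  mean annual OTM obtained by running the baseline-window temperatures
  (default 1950–1963) through the *current* climatology and risk curve
  with a fixed per-region reference MMTD (the study-period mean of
  predicted MMTD). Only the climate differs between the two terms, so
  EDM isolates the climate-change contribution; it is negative in years
  cooler than the baseline mean and is reported as-is. The published
  statewide series this package ships shows OTM − EDM constant across
  years to within ±1 death, which identifies the constant-baseline form;
  a year-matched-MMTD alternative is available via
  `RunConfig(baseline_mmtd="year_matched")`.

State-level (or any multi-region) totals are sums over regions.

## Key parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `summer_months` | {6,7,8,9} | — | months holding nearly all heat mortality in hot-summer US states; adding shoulder months changes totals by only a few percent |
| `ot_quantile` | 0.84 | — | standard MMT proxy percentile |
| `extreme_quantile` | 0.95 | — | conventional extreme-heat threshold |
| `climatology_window` | 2010–2023 | years | modern window reflecting present-day acclimatization; an earlier, cooler window lowers OT and raises attribution |
| `mmtd_fit_years` | 2013–2019 | years | excludes pandemic-era excess mortality while capturing population/health-care drift |
| `mmtd_window_halfwidth` | 2.0 | °C | wide enough for ≥30 qualifying days/year in most regions, narrow enough to stay near the mortality minimum |
| `edm_baseline_window` | 1950–1963 | years | mid-20th-century counterfactual; 1990–2003 supported as alternative |
| risk coefficients | shipped YAML | RR/°C, RR/°C² | see below |

### Risk coefficients

The coefficient constants of the published multi-city fits are not
printed in any source this package can ship, so the default file
`data/coefficients.yaml` contains package-calibrated stand-ins with the
same structure: A(SMT) = −0.0015·SMT + 0.0485 (RR per °C²) and
B(SMT) = −0.005·SMT + 0.19 (RR per °C). They were set once so that RR at
a typical extreme threshold (~2.5 °C above OT) spans ≈1.10–1.25 over the
SMT range of Texas-like summers (26–31 °C), with cooler regions steeper —
the diagnostic band reported for US county fits. Users with externally
fitted coefficients should replace the file; the code treats the
composite A and B as ground truth and never re-derives signs from any
rendered formula.

## MMTD estimation details

MMTD(y) is the mean daily death count on days with |T − OT| ≤ 2 °C,
computed over **all** calendar days of the year (not summer only) to
maximize sample size; a summer-only switch exists. Sparse region-years
(<5 qualifying days) retry at ±3 °C, then fall back to the pooled
day-weighted mean over all qualifying fit-window days. A straight line is
fit by ordinary least squares to the fit-window values; years inside the
window use their observed value, years outside use the line, floored at
0. Regions with fewer than two usable yearly values are dropped from
attribution with a logged exclusion.

## Synthetic scenarios and what they test

The generator emulates: a seasonal cosine peaking in early August (day
213, configurable) so the hottest days fall inside the summer window; a
linear warming trend; stationary AR(1) day-to-day noise with specified
standard deviation and lag-1 autocorrelation; a cross-region climate
gradient; Poisson daily death counts with mean MMTD_true(y)·RR_true(T)
(gamma-Poisson overdispersion optional); and official annual counts as a
fixed reporting fraction of true heat deaths. Scenario defaults (10
regions, 2010–2023, 20 °C mean, 9 °C amplitude, 2 °C noise with
autocorrelation 0.7, 0.3 °C/decade warming, 12 deaths/day baseline
drifting +0.1/yr, 16% reporting) describe a Texas-like state at reduced
region count.

It does **not** emulate spatial correlation between regions, demographic
structure, cause-of-death composition, reporting lags, or
temperature–mortality lag dynamics. Passing recovery tests therefore
demonstrate that the pipeline correctly inverts its own generative model
at realistic noise levels — not that the model is correct for any real
population.

`analytic_expected_hrd` provides the deterministic expectation of each
estimator given a realized temperature series (death draws are the only
remaining randomness). Two modes exist because the plug-in baseline is
not unbiased for MMTD_true: the ±2 °C window contains above-OT days where
RR > 1, inflating the estimated baseline by the window-mean RR (≈1–3%
under the defaults). `mmtd_mode="true"` returns the truth-level
attributable count; `mmtd_mode="estimator"` returns the exact expectation
of the pipeline's estimator, propagating the inflated window means
through the OLS extrapolation (exact because the whole estimator is
linear in the death counts). Recovery tests compare against the estimator
mode, with the scenario truth pinned to the empirical climatology of the
realized series so climatology estimation error does not confound the
Monte-Carlo comparison; OT/SMT estimation error is exercised separately
by scenarios whose truth is set independently of the empirical
percentiles.

## Numerical choices

- Quantiles: linear interpolation between closest ranks
  (h = (n−1)q + 1 on the sorted sample) — recorded in config metadata
  since percentile conventions differ across software.
- OT/P95 are computed over all calendar days of the window by default
  (`quantile_days="summer"` preserves the alternative); an all-days 84th
  percentile is consistent with published statewide OT levels, whereas a
  summer-only percentile would be several degrees hotter.
- Nearest-grid-point assignment uses great-circle (haversine) distance on
  a spherical Earth; distances within 1 mm count as ties, resolved to the
  lexicographically smallest (lat, lon).
- OLS trend fits use `numpy.polyfit` (degree 1); tests check it against
  the closed-form normal equations.
- HRD values stay real-valued (expected deaths) through the pipeline;
  rounding to whole deaths happens only in display formatting.
- Degenerate inputs: constant temperature series yield OT = P95 with a
  warning; empty climatology windows exclude the region; zero qualifying
  MMTD days trigger the fallback chain; negative MMTD predictions floor
  at 0 with a warning.

## Known limitations

- The shipped risk coefficients are calibrated stand-ins, not fitted to
  mortality data; absolute attribution levels from the defaults are
  illustrative until users supply fitted coefficients.
- The baseline-mortality model ignores seasonality and day-of-week
  structure within a year.
- EDM requires baseline-period temperatures; the package evaluates them
  with the current climatology by design, so it cannot quantify
  acclimatization change between the periods.
- Under-reporting emulation is a single multiplicative fraction; real
  certificate-attribution behaviour varies with temperature severity and
  improves over time.
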