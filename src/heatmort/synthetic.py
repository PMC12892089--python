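"""Synthetic county-scale temperature and mortality scenarios.

Generates datasets with the statistical structure the attribution
framework assumes — a mortality-minimizing temperature, risk rising
above it, and a year-varying baseline death rate — with every ground
truth known, so the full pipeline can be tested for parameter recovery
without any external data.

Temperature: per region, daily mean temperature is a seasonal cosine
plus an optional linear warming trend plus stationary AR(1) noise,

    T(d) = mean + offset_r + A cos(2*pi*(doy - peak_doy)/365.25)
           + warming * years_elapsed / 10 + e(d),
    e(d) = phi * e(d-1) + sqrt(1 - phi^2) * sigma * z(d),

so the noise has stationary standard deviation ``noise_sd`` and lag-1
autocorrelation ``noise_autocorr``. The peak day defaults to early
August (day 213) so the hottest days fall inside the June–September
summer window.

Mortality: daily death counts are Poisson (optionally gamma-Poisson
overdispersed) with mean MMTD_true(year) * RR_true(T), the generative
inverse of the attribution identity HRD = (RR - 1) * MMTD. Official
annual counts are emulated as a configurable reporting fraction of the
true heat-related deaths, mimicking death-certificate undercounting.

All draws are reproducible: the scenario seed spawns independent
deterministic substreams for temperature, mortality and official
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climatology import RiskCoefficients, empirical_quantile, relative_risk

__all__ = [
    "RiskTruth",
    "ScenarioConfig",
    "generate_temperature",
    "generate_mortality",
    "generate_official_counts",
    "analytic_expected_hrd",
]


@dataclass(frozen=True)
class RiskTruth:
    """True risk-curve parameters of a scenario.

    ``ot``/``smt`` are the base-region values; a region's climate offset
    shifts both. ``p95`` optionally pins the true extreme threshold —
    when None, the oracle uses the empirical 95th percentile of the
    generated series.
    """

    ot: float = 28.0
    smt: float = 28.5
    coefficients: RiskCoefficients | None = None
    p95: float | None = None

    def coeffs(self) -> RiskCoefficients:
        return (
            self.coefficients
            if self.coefficients is not None
            else RiskCoefficients.default()
        )


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a synthetic county scenario.

    Defaults emulate a Texas-like state: 10 regions spanning a ~2 °C
    climate gradient, 2010–2023, ~20 °C annual-mean temperature with a
    9 °C seasonal swing peaking in early August, day-to-day weather
    noise of 2 °C with lag-1 autocorrelation 0.7, a 0.3 °C/decade
    warming trend, a baseline death rate of 12/day drifting upward by
    0.1/day/year, and official counts reporting 16% of true HRD.
    """

    n_regions: int = 10
    years: tuple[int, int] = (2010, 2023)
    climate_mean: float = 20.0
    region_spread: float = 1.0  # regions span climate_mean ± spread
    seasonal_amplitude: float = 9.0
    peak_doy: int = 213
    noise_sd: float = 2.0
    noise_autocorr: float = 0.7
    warming_per_decade: float = 0.3
    mmtd_level: float = 12.0
    mmtd_drift_per_year: float = 0.1
    rr_truth: RiskTruth = field(default_factory=RiskTruth)
    overdispersion: float = 0.0  # 0 → Poisson; >0 → gamma-Poisson shape
    reporting_fraction: float = 0.16
    seed: int = 0
    # explicit per-region truth overriding the base-value + offset scheme
    ot_by_region: dict | None = None
    smt_by_region: dict | None = None
    p95_by_region: dict | None = None

    def __post_init__(self) -> None:
        for name in (
            "climate_mean", "region_spread", "seasonal_amplitude", "noise_sd",
            "noise_autocorr", "warming_per_decade", "mmtd_level",
            "mmtd_drift_per_year", "reporting_fraction", "overdispersion",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite scenario parameter {name}")
        if self.n_regions < 1:
            raise ValueError("n_regions must be positive")
        if self.years[1] < self.years[0]:
            raise ValueError(f"empty year range {self.years}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.noise_autocorr < 1.0:
            raise ValueError("noise_autocorr must lie in [0, 1)")
        if not 0.0 <= self.reporting_fraction <= 1.0:
            raise ValueError("reporting_fraction must lie in [0, 1]")

    # -- per-region ground truth -------------------------------------
    def region_ids(self) -> list[str]:
        return [f"R{i:02d}" for i in range(self.n_regions)]

    def region_offsets(self) -> np.ndarray:
        if self.n_regions == 1:
            return np.zeros(1)
        return np.linspace(-self.region_spread, self.region_spread, self.n_regions)

    def true_ot(self) -> pd.Series:
        if self.ot_by_region is not None:
            return pd.Series(self.ot_by_region, name="OT").loc[self.region_ids()]
        return pd.Series(
            self.rr_truth.ot + self.region_offsets(),
            index=self.region_ids(),
            name="OT",
        )

    def true_smt(self) -> pd.Series:
        if self.smt_by_region is not None:
            return pd.Series(self.smt_by_region, name="SMT").loc[self.region_ids()]
        return pd.Series(
            self.rr_truth.smt + self.region_offsets(),
            index=self.region_ids(),
            name="SMT",
        )

    def mmtd_true(self, year: int | np.ndarray) -> np.ndarray:
        """True baseline death rate for a year (same in every region)."""
        val = self.mmtd_level + self.mmtd_drift_per_year * (
            np.asarray(year, dtype=float) - self.years[0]
        )
        return val


def _rng(config: ScenarioConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *key])


def generate_temperature(config: ScenarioConfig) -> pd.DataFrame:
    """Daily mean temperature per region-day (long format)."""
    start = pd.Timestamp(f"{config.years[0]}-01-01")
    end = pd.Timestamp(f"{config.years[1]}-12-31")
    dates = pd.date_range(start, end, freq="D")
    doy = dates.day_of_year.to_numpy(dtype=float)
    elapsed_years = (dates - start).days.to_numpy(dtype=float) / 365.25
    seasonal = config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - config.peak_doy) / 365.25
    )
    trend = config.warming_per_decade * elapsed_years / 10.0
    phi = config.noise_autocorr
    parts = []
    for i, (region, offset) in enumerate(
        zip(config.region_ids(), config.region_offsets())
    ):
        rng = _rng(config, 0, i)
        z = rng.standard_normal(len(dates))
        noise = np.empty(len(dates))
        innov_sd = config.noise_sd * np.sqrt(1.0 - phi**2)
        # start at the stationary distribution
        noise[0] = config.noise_sd * z[0]
        for t in range(1, len(dates)):
            noise[t] = phi * noise[t - 1] + innov_sd * z[t]
        parts.append(
            pd.DataFrame(
                {
                    "region_id": region,
                    "date": dates,
                    "value": config.climate_mean + offset + seasonal + trend + noise,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def _true_rr(config: ScenarioConfig, region: str, T: np.ndarray) -> np.ndarray:
    ot = config.true_ot()[region]
    smt = config.true_smt()[region]
    return relative_risk(T, ot, smt, config.rr_truth.coeffs())


def generate_mortality(temps: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Daily death counts with mean MMTD_true(year) * RR_true(T)."""
    years_all = pd.to_datetime(temps["date"]).dt.year.to_numpy()
    if np.any(config.mmtd_true(np.unique(years_all)) <= 0):
        raise ValueError("MMTD_true must be positive for every scenario year")
    parts = []
    for i, region in enumerate(config.region_ids()):
        grp = temps[temps["region_id"] == region]
        if grp.empty:
            raise ValueError(f"no temperature series for region {region!r}")
        T = grp["value"].to_numpy(dtype=float)
        years = pd.to_datetime(grp["date"]).dt.year.to_numpy()
        mu = config.mmtd_true(years) * _true_rr(config, region, T)
        rng = _rng(config, 1, i)
        if config.overdispersion > 0:
            k = config.overdispersion
            lam = rng.gamma(shape=k, scale=mu / k)
            draws = rng.poisson(lam)
        else:
            draws = rng.poisson(mu)
        parts.append(
            pd.DataFrame(
                {"region_id": region, "date": grp["date"].to_numpy(), "value": draws}
            )
        )
    return pd.concat(parts, ignore_index=True)


def generate_official_counts(
    true_hrd_by_year: pd.Series,
    reporting_fraction: float,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Emulated official annual heat-death counts.

    Deterministically ``round(fraction * truth)`` per year; when a
    generator is supplied, Poisson counts with that mean instead.
    """
    if not 0.0 <= reporting_fraction <= 1.0:
        raise ValueError("reporting_fraction must lie in [0, 1]")
    truth = pd.Series(true_hrd_by_year, dtype=float)
    mean = reporting_fraction * truth
    if rng is None:
        counts = np.round(mean).astype(int)
    else:
        counts = rng.poisson(mean.to_numpy())
    return pd.Series(counts, index=truth.index, name="official")


def analytic_expected_hrd(
    temps: pd.DataFrame,
    config: ScenarioConfig,
    summer_months: tuple[int, ...] = (6, 7, 8, 9),
    baseline_years: tuple[int, int] | None = None,
    mmtd_mode: str = "true",
    mmtd_fit_years: tuple[int, int] = (2013, 2019),
    mmtd_halfwidth: float = 2.0,
) -> pd.DataFrame:
    """Deterministic expectation of the attribution estimators.

    Given the realized temperature series (the only randomness left is
    the death draws), the expected annual attributable deaths are

        E[OTM](r, y) = sum over summer days with T > OT_r of
                       (RR_true(T) - 1) * M(y)

    and E[XHM] restricts the sum to days with T at or above the true
    95th-percentile threshold (``rr_truth.p95`` shifted by the region
    offset, or the empirical 95th percentile of the region's series).

    ``mmtd_mode`` selects the baseline-mortality factor M(y):

    * ``"true"`` — the generative MMTD_true(y); the truth-level
      attributable-death count.
    * ``"estimator"`` — the exact expectation of the pipeline's plug-in
      baseline: for fit-window years, the mean of MMTD_true(y)·RR_true(T)
      over days with |T − OT| ≤ ``mmtd_halfwidth`` (the window includes
      above-OT days where RR > 1, so the plug-in baseline is slightly
      inflated); for other years the OLS line through those expectations
      (the estimator is linear in the death counts, so this propagation
      is exact; the sparse-data fallbacks are not modelled). This mode
      assumes the pipeline's OT equals the scenario's true OT, which
      holds when the truth is pinned to the empirical climatology.

    With ``baseline_years`` inside the series span, E[EDM] subtracts the
    mean annual expected OTM over that window evaluated with the fixed
    study-period-mean baseline. Used as the oracle in parameter-recovery
    tests.
    """
    if mmtd_mode not in ("true", "estimator"):
        raise ValueError("mmtd_mode must be 'true' or 'estimator'")
    rows = []
    coeffs = config.rr_truth.coeffs()
    for region in config.region_ids():
        grp = temps[temps["region_id"] == region]
        if grp.empty:
            continue
        dates = pd.to_datetime(grp["date"])
        T = grp["value"].to_numpy(dtype=float)
        ot = config.true_ot()[region]
        smt = config.true_smt()[region]
        if config.p95_by_region is not None:
            p95 = config.p95_by_region[region]
        elif config.rr_truth.p95 is not None:
            offset = config.true_ot()[region] - config.rr_truth.ot
            p95 = config.rr_truth.p95 + offset
        else:
            p95 = empirical_quantile(T, 0.95)
        rr = relative_risk(T, ot, smt, coeffs)
        is_summer = dates.dt.month.isin(summer_months).to_numpy()
        years = dates.dt.year.to_numpy()
        uniq_years = np.unique(years)
        excess = np.maximum(rr - 1.0, 0.0)
        otm_day = np.where(is_summer & (T > ot), excess, 0.0)
        xhm_day = np.where(is_summer & (T >= p95), excess, 0.0)

        if mmtd_mode == "true":
            exp_m = {int(y): float(config.mmtd_true(y)) for y in uniq_years}
        else:
            lo, hi = mmtd_fit_years
            fit_exp = {}
            for y in range(lo, hi + 1):
                qual = (years == y) & (np.abs(T - ot) <= mmtd_halfwidth)
                if qual.sum() == 0:
                    continue
                fit_exp[y] = float(config.mmtd_true(y)) * float(rr[qual].mean())
            slope, intercept = np.polyfit(
                np.array(list(fit_exp), dtype=float),
                np.array(list(fit_exp.values())),
                1,
            )
            exp_m = {
                int(y): fit_exp.get(int(y), max(slope * y + intercept, 0.0))
                for y in uniq_years
            }

        for year in uniq_years:
            sel = years == year
            mmtd = exp_m[int(year)]
            rows.append(
                {
                    "region_id": region,
                    "year": int(year),
                    "expected_otm": float(otm_day[sel].sum()) * mmtd,
                    "expected_xhm": float(xhm_day[sel].sum()) * mmtd,
                    "_unit_otm": float(otm_day[sel].sum()),  # per unit MMTD
                    "_exp_m": mmtd,
                }
            )
    out = pd.DataFrame(rows)
    if baseline_years is not None:
        lo, hi = baseline_years
        ref_mmtd = out.groupby("region_id")["_exp_m"].mean()
        base = out[(out["year"] >= lo) & (out["year"] <= hi)]
        baseline_const = base.groupby("region_id")["_unit_otm"].mean() * ref_mmtd
        out["expected_edm"] = out["expected_otm"] - out["region_id"].map(
            baseline_const
        ).astype(float)
    return out.drop(columns=["_unit_otm", "_exp_m"])
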