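"""Minimum-mortality-temperature death rate (MMTD) estimation.

MMTD(y, c) is the baseline daily death count for region c in year y: the
mean of daily all-cause deaths on days whose temperature lies within
±2 °C of the region's optimal temperature OT. It is observed directly
for each year of a fit window (default 2013–2019, excluding the
pandemic years) and linearly extrapolated outside it, which carries
long-term drift from population growth and healthcare change into the
early and late study years without importing pandemic-era excess
mortality.

Sparse regions: a region-year with fewer than ``min_days`` qualifying
days retries with a widened window (default ±3 °C), then falls back to
the pooled multi-year mean over all qualifying days of the fit window.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .config import RunConfig

__all__ = [
    "estimate_mmtd_year",
    "fit_mmtd_model",
    "predict_mmtd",
    "MMTDBaseline",
]


def estimate_mmtd_year(
    deaths: pd.DataFrame,
    temps: pd.DataFrame,
    ot: float,
    year: int,
    halfwidth: float = 2.0,
    summer_months: tuple[int, ...] | None = None,
) -> tuple[float, int]:
    """Mean daily deaths on near-OT days of one calendar year.

    ``deaths`` and ``temps`` are single-region daily series aligned on
    date. Days with |T − OT| ≤ halfwidth qualify; restrict to summer
    months by passing ``summer_months``. Returns ``(mmtd, n_days)``;
    ``(nan, 0)`` with a warning when no day qualifies.
    """
    merged = pd.merge(
        temps.rename(columns={"value": "T"}),
        deaths.rename(columns={"value": "deaths"}),
        on=["region_id", "date"] if "region_id" in temps.columns else ["date"],
        how="inner",
    )
    dates = pd.to_datetime(merged["date"])
    mask = (dates.dt.year == year) & ((merged["T"] - ot).abs() <= halfwidth)
    if summer_months is not None:
        mask &= dates.dt.month.isin(summer_months)
    sel = merged.loc[mask, "deaths"].dropna()
    if sel.empty:
        warnings.warn(
            f"no qualifying day within ±{halfwidth} °C of OT={ot:.2f} in {year}",
            stacklevel=2,
        )
        return float("nan"), 0
    return float(sel.mean()), int(len(sel))


def fit_mmtd_model(observed: dict[int, float]) -> tuple[float, float]:
    """OLS line (slope per year, intercept) through (year, MMTD) pairs.

    Requires at least two non-missing values.
    """
    pairs = [(y, v) for y, v in observed.items() if np.isfinite(v)]
    if len(pairs) < 2:
        raise ValueError(
            f"cannot fit MMTD trend from {len(pairs)} point(s); need >= 2"
        )
    years = np.array([p[0] for p in pairs], dtype=float)
    vals = np.array([p[1] for p in pairs], dtype=float)
    slope, intercept = np.polyfit(years, vals, 1)
    return float(slope), float(intercept)


def predict_mmtd(
    observed: dict[int, float], slope: float, intercept: float, year: int
) -> float:
    """Observed value inside the fit window, line prediction outside.

    Predictions are floored at 0 (a steep negative trend cannot produce
    a negative death rate).
    """
    if year in observed and np.isfinite(observed[year]):
        return float(observed[year])
    pred = slope * year + intercept
    if pred < 0:
        warnings.warn(f"MMTD prediction for {year} below zero; floored at 0", stacklevel=2)
        return 0.0
    return float(pred)


class MMTDBaseline(BaseEstimator):
    """Per-region yearly baseline-mortality model.

    Fit on long-format death counts (``X``) with the matching daily
    temperature table and a per-region climatology (for OT). For each
    region: yearly MMTD over the fit window, an OLS trend line, and the
    sparse-data fallbacks described in the module docstring.

    Attributes
    ----------
    observed_ : DataFrame (region_id, year, mmtd, n_days, source) of
        fit-window estimates; source is observed | widened | pooled.
    models_ : DataFrame indexed by region_id with slope and intercept.
    dropped_regions_ : regions excluded because no trend could be fit.
    """

    def __init__(
        self,
        fit_years: tuple[int, int] = (2013, 2019),
        halfwidth: float = 2.0,
        widened_halfwidth: float = 3.0,
        min_days: int = 5,
        window_days: str = "all",
        summer_months: tuple[int, ...] = (6, 7, 8, 9),
    ):
        self.fit_years = fit_years
        self.halfwidth = halfwidth
        self.widened_halfwidth = widened_halfwidth
        self.min_days = min_days
        self.window_days = window_days
        self.summer_months = summer_months

    @classmethod
    def from_config(cls, config: RunConfig) -> "MMTDBaseline":
        return cls(
            fit_years=config.mmtd_fit_years,
            halfwidth=config.mmtd_window_halfwidth,
            widened_halfwidth=config.mmtd_widened_halfwidth,
            min_days=config.mmtd_min_days,
            window_days=config.mmtd_window_days,
            summer_months=config.summer_months,
        )

    def fit(
        self, X: pd.DataFrame, y=None, *, temps: pd.DataFrame, climatology: pd.DataFrame
    ) -> "MMTDBaseline":
        deaths = X
        months = self.summer_months if self.window_days == "summer" else None
        lo, hi = self.fit_years
        obs_rows = []
        model_rows = {}
        dropped = []
        regions = [r for r in climatology.index if r in set(deaths["region_id"])]
        for region in regions:
            d = deaths[deaths["region_id"] == region]
            t = temps[temps["region_id"] == region]
            ot = float(climatology.loc[region, "OT"])
            observed: dict[int, float] = {}
            pooled_vals: list[tuple[float, int]] = []
            for year in range(lo, hi + 1):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    val, n = estimate_mmtd_year(
                        d, t, ot, year, self.halfwidth, summer_months=months
                    )
                source = "observed"
                if n < self.min_days:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        val, n = estimate_mmtd_year(
                            d, t, ot, year, self.widened_halfwidth, summer_months=months
                        )
                    source = "widened"
                if n > 0:
                    # every qualifying day feeds the pooled fallback mean
                    pooled_vals.append((val, n))
                if n < self.min_days:
                    val, source = float("nan"), "pooled"
                obs_rows.append(
                    {"region_id": region, "year": year, "mmtd": val,
                     "n_days": n, "source": source}
                )
                if np.isfinite(val):
                    observed[year] = val
            # pooled fallback: weighted mean over all qualifying fit-window days
            if pooled_vals:
                tot_n = sum(n for _, n in pooled_vals)
                pooled_mean = sum(v * n for v, n in pooled_vals) / tot_n
                for row in obs_rows:
                    if row["region_id"] == region and row["source"] == "pooled":
                        row["mmtd"] = pooled_mean
                        observed[row["year"]] = pooled_mean
            try:
                slope, intercept = fit_mmtd_model(observed)
            except ValueError:
                warnings.warn(
                    f"region {region!r}: MMTD trend unfittable; region dropped "
                    "from attribution",
                    stacklevel=2,
                )
                dropped.append(region)
                continue
            model_rows[region] = {"slope": slope, "intercept": intercept}
        if not model_rows:
            raise ValueError("no region yielded a fittable MMTD model")
        self.observed_ = pd.DataFrame(obs_rows)
        self.models_ = pd.DataFrame.from_dict(model_rows, orient="index").rename_axis(
            "region_id"
        )
        self.dropped_regions_ = dropped
        self._observed_maps_ = {
            region: {
                int(r["year"]): float(r["mmtd"])
                for _, r in self.observed_[self.observed_["region_id"] == region].iterrows()
                if np.isfinite(r["mmtd"])
            }
            for region in self.models_.index
        }
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "models_"):
            raise NotFittedError("MMTDBaseline is not fitted yet; call fit first")

    def predict(self, region_id: str, year: int) -> float:
        """MMTD for one region-year (observed in-window, line outside)."""
        self._check_fitted()
        if region_id not in self.models_.index:
            raise KeyError(f"region {region_id!r} has no MMTD model")
        row = self.models_.loc[region_id]
        return predict_mmtd(
            self._observed_maps_[region_id], row["slope"], row["intercept"], year
        )

    def predict_table(self, years) -> pd.DataFrame:
        """MMTD for every modelled region over ``years`` (long format)."""
        self._check_fitted()
        lo, hi = self.fit_years
        rows = []
        for region in self.models_.index:
            for year in years:
                rows.append(
                    {
                        "region_id": region,
                        "year": int(year),
                        "mmtd": self.predict(region, int(year)),
                        "source": "observed" if lo <= year <= hi else "extrapolated",
                    }
                )
        return pd.DataFrame(rows)
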