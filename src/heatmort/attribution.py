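"""Daily heat-related deaths and the three attribution estimators.

Daily attributable deaths for a region on a summer day with temperature
T are

    HRD = (RR(T) - 1) * MMTD(y)

with RR the region's relative-risk curve (1 at or below OT) and MMTD(y)
the year's baseline death rate, so HRD is a real-valued expected death
count, zero at or below OT.

Aggregation conventions:

* OTM (optimal temperature method) — sum of HRD over summer days with
  T > OT; counts moderate and extreme heat alike.
* XHM (extreme heat method) — the same sum restricted to days with
  T ≥ the region's 95th-percentile threshold.
* EDM (excess death method) — OTM in the study period minus the mean
  annual OTM under the climate of a historical baseline window,
  evaluated with the *current* climatology and risk curve and a fixed
  study-period reference MMTD, so the counterfactual changes only the
  climate. EDM may be negative in years cooler than the baseline mean.

State (or any multi-region) totals are sums over regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .climatology import RiskCoefficients, TemperatureClimatology, relative_risk
from .config import RunConfig
from .mmtd import MMTDBaseline

__all__ = [
    "daily_hrd",
    "aggregate_otm",
    "aggregate_xhm",
    "compute_baseline_otm",
    "compute_edm",
    "HeatAttributionModel",
]

STATE_SCOPE = "state"


def daily_hrd(
    temps: pd.DataFrame,
    climatology: pd.DataFrame,
    mmtd_table: pd.DataFrame,
    coeffs: RiskCoefficients,
    summer_months: tuple[int, ...] = (6, 7, 8, 9),
) -> pd.DataFrame:
    """Per-day attributable deaths for every region-day.

    ``temps`` is a long-format temperature table; ``climatology`` a
    per-region OT/SMT/P95 frame; ``mmtd_table`` long-format
    (region_id, year, mmtd). Returns one row per region-day with
    columns T, rr, mmtd, hrd and the flags is_summer, exceeds_ot,
    exceeds_p95. Non-summer days carry hrd = 0 and rr evaluated anyway
    for diagnostics. Regions without climatology or MMTD are omitted.
    """
    if (mmtd_table["mmtd"].dropna() < 0).any():
        raise ValueError("negative MMTD value")
    out_parts = []
    mmtd_lookup = mmtd_table.set_index(["region_id", "year"])["mmtd"]
    for region, grp in temps.groupby("region_id", sort=True):
        if region not in climatology.index:
            continue
        clim = climatology.loc[region]
        dates = pd.to_datetime(grp["date"])
        years = dates.dt.year.to_numpy()
        T = grp["value"].to_numpy(dtype=float)
        try:
            mmtd = np.array(
                [mmtd_lookup.get((region, y), np.nan) for y in years], dtype=float
            )
        except KeyError:  # pragma: no cover
            continue
        if np.all(np.isnan(mmtd)):
            continue
        rr = relative_risk(T, clim["OT"], clim["SMT"], coeffs)
        is_summer = dates.dt.month.isin(summer_months).to_numpy()
        hrd = np.where(is_summer, np.maximum(rr - 1.0, 0.0) * mmtd, 0.0)
        hrd = np.where(np.isnan(hrd) & ~is_summer, 0.0, hrd)
        out_parts.append(
            pd.DataFrame(
                {
                    "region_id": region,
                    "date": dates.to_numpy(),
                    "year": years,
                    "T": T,
                    "rr": rr,
                    "mmtd": mmtd,
                    "hrd": hrd,
                    "is_summer": is_summer,
                    "exceeds_ot": T > clim["OT"],
                    "exceeds_p95": T >= clim["P95"],
                }
            )
        )
    if not out_parts:
        raise ValueError("no region had both climatology and MMTD data")
    return pd.concat(out_parts, ignore_index=True)


def _aggregate(daily: pd.DataFrame, mask: np.ndarray) -> pd.DataFrame:
    sel = daily.loc[mask, ["region_id", "year", "hrd"]]
    per_region = (
        sel.groupby(["region_id", "year"], sort=True)["hrd"].sum().reset_index()
    )
    # region-years present in daily but with no qualifying day contribute 0
    all_keys = daily[["region_id", "year"]].drop_duplicates()
    per_region = all_keys.merge(per_region, on=["region_id", "year"], how="left").fillna(
        {"hrd": 0.0}
    )
    state = per_region.groupby("year", sort=True)["hrd"].sum().reset_index()
    state.insert(0, "region_id", STATE_SCOPE)
    return pd.concat([per_region, state], ignore_index=True).rename(
        columns={"region_id": "scope"}
    )


def aggregate_otm(daily: pd.DataFrame) -> pd.DataFrame:
    """Annual OTM per scope: HRD summed over summer days with T > OT."""
    mask = (daily["is_summer"] & daily["exceeds_ot"]).to_numpy()
    return _aggregate(daily, mask).rename(columns={"hrd": "otm"})


def aggregate_xhm(daily: pd.DataFrame) -> pd.DataFrame:
    """Annual XHM per scope: HRD summed over summer days with T ≥ P95."""
    mask = (daily["is_summer"] & daily["exceeds_p95"]).to_numpy()
    return _aggregate(daily, mask).rename(columns={"hrd": "xhm"})


def compute_baseline_otm(
    baseline_temps: pd.DataFrame,
    climatology: pd.DataFrame,
    coeffs: RiskCoefficients,
    reference_mmtd: pd.Series,
    summer_months: tuple[int, ...] = (6, 7, 8, 9),
) -> pd.Series:
    """Mean annual summertime OTM under a baseline-period climate.

    The baseline temperatures are evaluated against the *current*
    climatology (OT, SMT) and risk curve, with a fixed per-region
    ``reference_mmtd`` (deaths/day), so only the climate differs from
    the study-period calculation. Returns one constant per scope
    (every region plus the state total).
    """
    if baseline_temps.empty:
        raise ValueError("empty baseline temperature window")
    years = pd.to_datetime(baseline_temps["date"]).dt.year
    mmtd_table = pd.DataFrame(
        [
            {"region_id": r, "year": y, "mmtd": reference_mmtd[r]}
            for r in reference_mmtd.index
            for y in sorted(years.unique())
        ]
    )
    daily = daily_hrd(baseline_temps, climatology, mmtd_table, coeffs, summer_months)
    otm = aggregate_otm(daily)
    return otm.groupby("scope", sort=True)["otm"].mean().rename("otm_baseline")


def compute_edm(otm_by_year: pd.DataFrame, otm_baseline: pd.Series) -> pd.DataFrame:
    """EDM per scope-year: OTM(year) minus the scope's baseline constant.

    Negative values (years cooler than the baseline mean) are preserved.
    """
    out = otm_by_year.copy()
    out["edm"] = out["otm"] - out["scope"].map(otm_baseline).astype(float)
    return out[["scope", "year", "edm"]]


class HeatAttributionModel(BaseEstimator):
    """End-to-end attribution: climatology + MMTD + OTM/XHM/(EDM).

    Fit on study-period daily temperatures (``X``) and death counts
    (``y``), both long-format. Fitting estimates the per-region
    climatology and MMTD model and produces the study-period HRD table;
    :meth:`add_edm` augments it with excess deaths relative to a
    baseline-period temperature series.

    Attributes
    ----------
    climatology_ : fitted :class:`TemperatureClimatology`.
    mmtd_ : fitted :class:`MMTDBaseline`.
    daily_ : per-day attribution frame (see :func:`daily_hrd`).
    hrd_table_ : per-scope-per-year table with otm and xhm columns
        (plus edm after :meth:`add_edm`).
    """

    def __init__(
        self,
        config: RunConfig | None = None,
        coefficients: RiskCoefficients | None = None,
        study_years: tuple[int, int] | None = None,
    ):
        self.config = config
        self.coefficients = coefficients
        self.study_years = study_years

    def _cfg(self) -> RunConfig:
        return self.config if self.config is not None else RunConfig()

    def _coeffs(self) -> RiskCoefficients:
        return (
            self.coefficients
            if self.coefficients is not None
            else RiskCoefficients.default()
        )

    def fit(self, X: pd.DataFrame, y: pd.DataFrame) -> "HeatAttributionModel":
        cfg = self._cfg()
        temps, deaths = X, y
        self.climatology_ = TemperatureClimatology.from_config(
            cfg, coefficients=self._coeffs()
        ).fit(temps)
        clim = self.climatology_.climatology_
        self.mmtd_ = MMTDBaseline.from_config(cfg).fit(
            deaths, temps=temps, climatology=clim
        )
        years_present = sorted(pd.to_datetime(temps["date"]).dt.year.unique())
        if self.study_years is not None:
            lo, hi = self.study_years
            years = [y for y in years_present if lo <= y <= hi]
        else:
            years = years_present
        self.years_ = years
        mmtd_table = self.mmtd_.predict_table(years)
        study_temps = temps[pd.to_datetime(temps["date"]).dt.year.isin(years)]
        self.daily_ = daily_hrd(
            study_temps,
            clim.loc[clim.index.isin(self.mmtd_.models_.index)],
            mmtd_table,
            self._coeffs(),
            cfg.summer_months,
        )
        otm = aggregate_otm(self.daily_)
        xhm = aggregate_xhm(self.daily_)
        self.hrd_table_ = otm.merge(xhm, on=["scope", "year"])
        self.reference_mmtd_ = (
            mmtd_table.groupby("region_id")["mmtd"].mean().rename("reference_mmtd")
        )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "hrd_table_"):
            raise NotFittedError("HeatAttributionModel is not fitted yet")

    def add_edm(self, baseline_temps: pd.DataFrame) -> pd.DataFrame:
        """Compute EDM against a baseline-climate temperature series and
        merge it into ``hrd_table_``."""
        self._check_fitted()
        cfg = self._cfg()
        clim = self.climatology_.climatology_
        clim = clim.loc[clim.index.isin(self.mmtd_.models_.index)]
        if cfg.baseline_mmtd == "fixed":
            ref = self.reference_mmtd_
            self.otm_baseline_ = compute_baseline_otm(
                baseline_temps, clim, self._coeffs(), ref, cfg.summer_months
            )
        else:  # year_matched: baseline years cycle through study-year MMTDs
            per_year = []
            b_years = sorted(pd.to_datetime(baseline_temps["date"]).dt.year.unique())
            for i, by in enumerate(b_years):
                sy = self.years_[i % len(self.years_)]
                ref = pd.Series(
                    {
                        r: self.mmtd_.predict(r, sy)
                        for r in self.mmtd_.models_.index
                    }
                )
                sel = baseline_temps[
                    pd.to_datetime(baseline_temps["date"]).dt.year == by
                ]
                per_year.append(
                    compute_baseline_otm(
                        sel, clim, self._coeffs(), ref, cfg.summer_months
                    )
                )
            self.otm_baseline_ = (
                pd.concat(per_year, axis=1).mean(axis=1).rename("otm_baseline")
            )
        otm = self.hrd_table_[["scope", "year", "otm"]]
        edm = compute_edm(otm, self.otm_baseline_)
        self.hrd_table_ = self.hrd_table_.drop(columns=["edm"], errors="ignore").merge(
            edm, on=["scope", "year"]
        )
        return self.hrd_table_

    def attach_official(self, official: pd.DataFrame) -> pd.DataFrame:
        """Merge official annual counts (columns region_id/year/count);
        region_id ``statewide`` maps onto the state scope row."""
        self._check_fitted()
        off = official.copy()
        off["scope"] = off["region_id"].replace({"statewide": STATE_SCOPE})
        self.hrd_table_ = self.hrd_table_.drop(
            columns=["official"], errors="ignore"
        ).merge(
            off[["scope", "year", "count"]].rename(columns={"count": "official"}),
            on=["scope", "year"],
            how="left",
        )
        return self.hrd_table_
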