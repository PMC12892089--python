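"""Run configuration for the attribution pipeline.

All analysis choices that the attribution framework leaves open — the
summer window, the quantile levels defining the optimal temperature (OT)
and the extreme-heat threshold, the reference windows for climatology,
baseline-mortality fitting and the counterfactual climate — live here so
that every stage of the pipeline reads the same conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

YearRange = tuple[int, int]


def _check_range(name: str, rng: YearRange) -> tuple[int, int]:
    lo, hi = int(rng[0]), int(rng[1])
    if hi < lo:
        raise ValueError(f"{name} is empty: {rng!r}")
    return lo, hi


@dataclass
class RunConfig:
    """Shared analysis conventions.

    Parameters
    ----------
    summer_months : months counted as summertime (June–September).
    ot_quantile : quantile of daily mean temperature defining the optimal
        temperature OT (minimum-mortality temperature), default 0.84.
    extreme_quantile : quantile defining the extreme-heat threshold P95.
    climatology_window : inclusive year range over which OT, SMT and P95
        are computed, default 2010–2023.
    mmtd_fit_years : inclusive year range over which yearly baseline
        mortality (MMTD) is observed; other years are linearly
        extrapolated. Default 2013–2019, which deliberately excludes the
        pandemic years.
    mmtd_window_halfwidth : half-width in °C of the temperature window
        around OT used to estimate MMTD, default 2.0.
    edm_baseline_window : counterfactual-climate year range for the
        excess-death method, default 1950–1963 (alternate 1990–2003).
    quantile_days : "all" computes OT/P95 over every calendar day in the
        climatology window; "summer" restricts to summer months.
    mmtd_window_days : same switch for the MMTD estimation window.
    baseline_mmtd : "fixed" evaluates the counterfactual-baseline OTM
        with a single study-period-mean MMTD per region; "year_matched"
        re-uses each study year's MMTD.
    mmtd_min_days / mmtd_widened_halfwidth : sparse-data fallback — a
        region-year with fewer qualifying days than ``mmtd_min_days``
        retries with the widened half-width, then falls back to the
        pooled multi-year mean.
    """

    summer_months: tuple[int, ...] = (6, 7, 8, 9)
    ot_quantile: float = 0.84
    extreme_quantile: float = 0.95
    climatology_window: YearRange = (2010, 2023)
    mmtd_fit_years: YearRange = (2013, 2019)
    mmtd_window_halfwidth: float = 2.0
    edm_baseline_window: YearRange = (1950, 1963)
    quantile_days: str = "all"
    mmtd_window_days: str = "all"
    baseline_mmtd: str = "fixed"
    mmtd_min_days: int = 5
    mmtd_widened_halfwidth: float = 3.0
    coefficients_path: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.ot_quantile < self.extreme_quantile < 1.0:
            raise ValueError(
                "require 0 < ot_quantile < extreme_quantile < 1, got "
                f"{self.ot_quantile} and {self.extreme_quantile}"
            )
        self.climatology_window = _check_range("climatology_window", self.climatology_window)
        self.mmtd_fit_years = _check_range("mmtd_fit_years", self.mmtd_fit_years)
        self.edm_baseline_window = _check_range("edm_baseline_window", self.edm_baseline_window)
        self.summer_months = tuple(sorted(int(m) for m in self.summer_months))
        if any(m < 1 or m > 12 for m in self.summer_months) or not self.summer_months:
            raise ValueError(f"invalid summer_months {self.summer_months!r}")
        for key in ("quantile_days", "mmtd_window_days"):
            if getattr(self, key) not in ("all", "summer"):
                raise ValueError(f"{key} must be 'all' or 'summer'")
        if self.baseline_mmtd not in ("fixed", "year_matched"):
            raise ValueError("baseline_mmtd must be 'fixed' or 'year_matched'")
        if self.mmtd_window_halfwidth < 0 or self.mmtd_widened_halfwidth < 0:
            raise ValueError("MMTD window half-widths must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("climatology_window", "mmtd_fit_years", "edm_baseline_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "summer_months" in raw:
            raw["summer_months"] = tuple(raw["summer_months"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def years(self, window: YearRange) -> range:
        return range(window[0], window[1] + 1)
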